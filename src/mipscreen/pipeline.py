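"""End-to-end orchestration: simulate -> normalize/call -> triage -> resolve.

``run_pipeline`` chains the library stages and writes a reproducible
report bundle (decision TSVs, VCFs, BED, summary JSON, markdown report),
every file stamped with the configuration hash.  With ``simulate=True``
the inputs come from the packaged study-mirror cohort generator; otherwise
coverage/variant/manifest tables are read from disk.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path

import pandas as pd

from . import io as mio
from .cnv import annotate_cnv, call_cnvs, cnv_calls_to_frame, low_coverage_report, normalize
from .config import PipelineConfig
from .genemodel import GeneModel, build_fixture_gene_model, write_gene_model_tsv
from .panel import MipPanel, tile_panel, write_panel_bed
from .resolve import build_case_genotypes, resolve_case, summarize_cohort
from .simulate import CoverageSimSpec, mirror_cohort
from .triage import funnel_counts, triage_table

logger = logging.getLogger(__name__)


def _cnv_allele_stats(resolutions) -> dict:
    """Count CNV alleles (homozygous = 2) and distinct CNV events."""
    n_alleles = 0
    distinct = set()
    for r in resolutions:
        for a in r.alleles:
            if a.is_cnv:
                n_alleles += a.count
                distinct.add(a.description)
    return {"cnv_alleles": n_alleles, "cnv_distinct": len(distinct)}


def run_pipeline(config: PipelineConfig, out_dir: str | Path, *,
                 simulate: bool = False,
                 coverage: pd.DataFrame | str | Path | None = None,
                 variants: pd.DataFrame | str | Path | None = None,
                 manifest: pd.DataFrame | str | Path | None = None,
                 cnv_flags: pd.DataFrame | str | Path | None = None,
                 panel: MipPanel | None = None,
                 model: GeneModel | None = None) -> dict:
    """Run the full screening analysis and write the report bundle.

    Returns a dict with the in-memory results (decisions, cnv_calls,
    resolutions, summary, ...).  Idempotent for a fixed config and seed.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    model = model or build_fixture_gene_model(config.seed)
    panel = panel or tile_panel(model)

    truth = None
    if simulate:
        sim_spec = CoverageSimSpec(mean_depth=config.mean_depth,
                                   dispersion=config.dispersion,
                                   efficiency_sigma=config.efficiency_sigma)
        truth, table, cov = mirror_cohort(
            panel, model, seed=config.seed,
            benign_fraction=config.benign_fraction, sim_spec=sim_spec)
        manifest_df = truth.manifest
        flags_df = truth.cnv_flags
        truth.to_json(out / "truth.json")
    else:
        if coverage is None or variants is None or manifest is None:
            raise ValueError("coverage, variants and manifest are required "
                             "unless simulate=True")
        cov = coverage if isinstance(coverage, pd.DataFrame) else mio.read_coverage(coverage)
        table = variants if isinstance(variants, pd.DataFrame) else mio.read_variants_tsv(variants)
        manifest_df = (manifest if isinstance(manifest, pd.DataFrame)
                       else pd.read_csv(manifest, sep="\t", comment="#"))
        if cnv_flags is None:
            flags_df = None
        else:
            flags_df = (cnv_flags if isinstance(cnv_flags, pd.DataFrame)
                        else pd.read_csv(cnv_flags, sep="\t", comment="#"))

    # coverage stage
    norm = normalize(cov, median_floor=config.median_floor)
    calls = call_cnvs(norm, del_thresh=config.del_thresh,
                      dup_thresh=config.dup_thresh, min_run=config.min_run)
    calls = [annotate_cnv(c, panel, model) for c in calls]
    lowcov = low_coverage_report(cov, manual_thresh=config.manual_cov,
                                 sanger_thresh=config.sanger_cov)

    # triage stage
    decisions = triage_table(table, panel, max_maf=config.max_maf,
                             min_rf=config.min_rf,
                             min_delta=config.spliceai_delta,
                             min_hits=config.spliceai_hits,
                             min_criteria=config.missense_min_criteria)
    funnel = funnel_counts(decisions)

    # resolution stage
    genotypes = build_case_genotypes(manifest_df, decisions, calls, flags_df)
    resolutions = [resolve_case(g) for g in genotypes]
    summary = summarize_cohort(resolutions, convention=config.percent_convention)

    summary_payload = {
        "total": summary.total,
        "counts": summary.counts,
        "solved_inclusive": summary.solved_inclusive,
        "solved_strict": summary.solved_strict,
        "percent_solved": summary.percent_solved,
        "percent_by_phenotype": summary.percent_by_phenotype,
        "wgs_referrals": summary.referrals,
        "n_wgs_referrals": len(summary.referrals),
        "percent_convention": summary.convention,
        "config_hash": config.hash,
        **_cnv_allele_stats(resolutions),
        "funnel": funnel,
    }

    # report bundle
    config.to_yaml(out / "config.yaml")
    write_gene_model_tsv(model, out / "gene_model.tsv")
    write_panel_bed(panel, out / "panel.bed", contig=model.contig)
    mio.write_coverage(cov, out / "coverage.tsv", config)
    mio.write_variants_tsv(table, out / "variants.tsv", config)
    mio.write_variants_vcf(table, out / "variants.vcf", model, config)
    mio.write_variants_tsv(decisions, out / "decisions.tsv", config)
    cnv_df = cnv_calls_to_frame(calls)
    mio.write_variants_tsv(cnv_df, out / "cnv_calls.tsv", config)
    mio.write_cnv_vcf(calls, out / "cnv_calls.vcf", model, panel, config)
    mio.write_variants_tsv(mio.low_coverage_to_frame(lowcov),
                           out / "low_coverage.tsv", config)
    mio.write_low_coverage_bed(lowcov, out / "low_coverage.bed", panel, model.contig)
    res_df = pd.DataFrame([
        {"sample_id": r.sample_id, "phenotype": r.phenotype, "status": r.status,
         "n_plp_alleles": r.n_plp_alleles, "n_qualifying_vus": r.n_qualifying_vus,
         "wgs_referral": r.wgs_referral,
         "alleles": ";".join(f"{a.description}[{a.tier}]" +
                             ("(hom)" if a.homozygous else "")
                             for a in r.alleles)}
        for r in resolutions])
    mio.write_variants_tsv(res_df, out / "resolutions.tsv", config)
    mio.write_variants_tsv(manifest_df, out / "manifest.tsv", config)
    (out / "summary.json").write_text(json.dumps(summary_payload, indent=1))
    (out / "report.md").write_text(_render_report(config, summary_payload,
                                                  res_df, cnv_df, funnel))
    return {"config": config, "model": model, "panel": panel, "coverage": cov,
            "normalized": norm, "cnv_calls": calls, "low_coverage": lowcov,
            "variants": table, "decisions": decisions, "manifest": manifest_df,
            "resolutions": resolutions, "summary": summary,
            "summary_payload": summary_payload, "truth": truth}


def _render_report(config: PipelineConfig, summary: dict, res_df: pd.DataFrame,
                   cnv_df: pd.DataFrame, funnel: dict) -> str:
    lines = [
        "# MIP screening report",
        "",
        f"Configuration hash: `{config.hash}`",
        "",
        "## Cohort summary",
        "",
        f"- cases: {summary['total']}",
        f"- solved (biallelic P/LP): {summary['solved_strict']}",
        f"- solved incl. qualifying VUS: {summary['solved_inclusive']} "
        f"({summary['percent_solved']}%)",
    ]
    for ph, pct in summary["percent_by_phenotype"].items():
        lines.append(f"- solve rate {ph}: {pct}%")
    lines += [
        f"- CNV alleles: {summary['cnv_alleles']} across "
        f"{summary['cnv_distinct']} distinct CNVs",
        f"- WGS referrals: {summary['n_wgs_referrals']} "
        f"({', '.join(summary['wgs_referrals'])})",
        "",
        "## Variant funnel",
        "",
    ]
    lines += [f"- {k}: {v}" for k, v in funnel.items()]
    lines += ["", "## Per-case evidence", ""]
    lines.append("```\n" + res_df.to_string(index=False) + "\n```")
    lines += ["", "## CNV calls", ""]
    lines.append("```\n" + cnv_df.to_string(index=False) + "\n```"
                 if len(cnv_df) else "none")
    lines.append("")
    return "\n".join(lines)
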