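"""Readers and writers for the pipeline's on-disk formats.

Tab-separated tables (UTF-8, header row, ``#``-prefixed provenance lines)
for coverage matrices, variant tables and decision trails; VCF 4.2 for
variant exchange (via pysam, against the declared synthetic contig — the
header names the pseudo-genome precisely so the files cannot silently be
confused with calls on a real reference); BED for low-coverage regions;
JSON for cohort summaries.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd
import pysam

from .cnv import CnvCall, LowCoverageRegion
from .config import PipelineConfig
from .genemodel import GeneModel

logger = logging.getLogger(__name__)

VCF_INFO_FIELDS = [
    # (id, number, type, description)
    ("HGVSC", "1", "String", "Coding HGVS"),
    ("HGVSP", "1", "String", "Protein HGVS"),
    ("CSQ", "1", "String", "Consequence class"),
    ("MAF", "1", "Float", "Population minor allele frequency"),
    ("RF", "1", "Float", "Alternate-allele read fraction"),
    ("GRANTHAM", "1", "Integer", "Grantham distance"),
    ("CADD", "1", "Float", "CADD PHRED score"),
    ("PHYLOP", "1", "Float", "PhyloP conservation score"),
    ("SIFT", "1", "String", "SIFT label"),
    ("MTASTER", "1", "String", "MutationTaster label"),
    ("SAI_AG", "1", "Float", "Splice delta: acceptor gain"),
    ("SAI_AL", "1", "Float", "Splice delta: acceptor loss"),
    ("SAI_DG", "1", "Float", "Splice delta: donor gain"),
    ("SAI_DL", "1", "Float", "Splice delta: donor loss"),
    ("DBSTAT", "1", "String", "Database status (LOVD/ClinVar label)"),
    ("CIS", "0", "Flag", "In cis with a stop-gain variant"),
    ("CONF", "0", "Flag", "Splice effect functionally confirmed"),
    ("HOM", "0", "Flag", "Homozygous by orthogonal evidence"),
    ("SAMPLE", "1", "String", "Sample identifier"),
    ("SUPPORT", "1", "String", "Per-probe variant support map"),
]

_TSV_TO_INFO = {
    "hgvs_c": "HGVSC", "hgvs_p": "HGVSP", "consequence": "CSQ", "maf": "MAF",
    "read_fraction": "RF", "grantham": "GRANTHAM", "cadd": "CADD",
    "phylop": "PHYLOP", "sift": "SIFT", "mtaster": "MTASTER",
    "sai_ag": "SAI_AG", "sai_al": "SAI_AL", "sai_dg": "SAI_DG",
    "sai_dl": "SAI_DL", "db_status": "DBSTAT", "sample_id": "SAMPLE",
    "probe_support": "SUPPORT",
}
_INFO_TO_TSV = {v: k for k, v in _TSV_TO_INFO.items()}


# -- generic TSV with provenance header -------------------------------

def _write_tsv(df: pd.DataFrame, path: str | Path, config: PipelineConfig | None,
               index: bool = False) -> None:
    with open(path, "w") as fh:
        if config is not None:
            fh.write(config.header_line() + "\n")
        df.to_csv(fh, sep="\t", index=index)


def _read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)


# -- coverage matrix ---------------------------------------------------

def write_coverage(cov: pd.DataFrame, path: str | Path,
                   config: PipelineConfig | None = None) -> None:
    _write_tsv(cov, path, config, index=True)


def read_coverage(path: str | Path) -> pd.DataFrame:
    """Read a samples x MIPs count matrix; ragged rows raise with the line."""
    rows, header = [], None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("#") or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if header is None:
                header = fields
                continue
            if len(fields) != len(header):
                raise ValueError(
                    f"{path}: line {lineno}: expected {len(header)} fields, "
                    f"got {len(fields)}")
            rows.append(fields)
    if header is None:
        raise ValueError(f"{path}: empty coverage file")
    df = pd.DataFrame(rows, columns=header).set_index(header[0])
    df.index.name = "sample_id"
    return df.astype(int)


# -- variant tables ----------------------------------------------------

def write_variants_tsv(table: pd.DataFrame, path: str | Path,
                       config: PipelineConfig | None = None) -> None:
    _write_tsv(table, path, config)


def read_variants_tsv(path: str | Path) -> pd.DataFrame:
    df = _read_tsv(path)
    for col in ("in_cis_with_stopgain", "functionally_confirmed", "homozygous"):
        if col in df:
            df[col] = df[col].astype(bool)
    return df


def _vcf_header(model: GeneModel, config: PipelineConfig | None) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    contig_len = model.exons[-1].genomic_end + 5000
    header.add_line(f"##contig=<ID={model.contig},length={contig_len}>")
    header.add_line(
        f"##reference=synthetic:{model.gene_id} (pseudo-genome; coordinates are "
        "NOT a real assembly)")
    if config is not None:
        header.add_line(f"##mipscreen_config_hash={config.hash}")
    for fid, number, ftype, desc in VCF_INFO_FIELDS:
        header.add_line(
            f'##INFO=<ID={fid},Number={number},Type={ftype},Description="{desc}">')
    for fid in ("SVTYPE",):
        header.add_line(
            f'##INFO=<ID={fid},Number=1,Type=String,Description="SV type">')
    header.add_line('##INFO=<ID=END,Number=1,Type=Integer,Description="SV end">')
    header.add_line('##INFO=<ID=NMIPS,Number=1,Type=Integer,Description="MIPs in run">')
    header.add_line('##INFO=<ID=MEANRATIO,Number=1,Type=Float,Description="Mean normalized coverage">')
    header.add_line('##INFO=<ID=IMPRECISE,Number=0,Type=Flag,Description="Breakpoints not base-resolved">')
    return header


def write_variants_vcf(table: pd.DataFrame, path: str | Path, model: GeneModel,
                       config: PipelineConfig | None = None) -> None:
    """Write the annotated variant table as VCF 4.2 on the synthetic contig."""
    header = _vcf_header(model, config)
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for _, row in table.iterrows():
            pos = int(row["genomic_pos"])
            ref = str(row.get("ref") or "N")
            alt = str(row.get("alt") or "")
            rec = vcf.new_record(
                contig=model.contig, start=pos - 1, stop=pos,
                alleles=(ref if ref not in ("", "nan") else "N",
                         alt if alt not in ("", "nan") else "<ALT>"))
            for col, key in _TSV_TO_INFO.items():
                val = row.get(col)
                if val is None or (isinstance(val, float) and pd.isna(val)) or val == "":
                    continue
                rec.info[key] = val if not isinstance(val, str) else val.replace(" ", "_")
            if bool(row.get("in_cis_with_stopgain")):
                rec.info["CIS"] = True
            if bool(row.get("functionally_confirmed")):
                rec.info["CONF"] = True
            if bool(row.get("homozygous")):
                rec.info["HOM"] = True
            vcf.write(rec)


def read_variants_vcf(path: str | Path) -> pd.DataFrame:
    """Read a VCF written by :func:`write_variants_vcf` back into a table.

    Unknown INFO keys are preserved nowhere but logged as a warning."""
    rows = []
    known = {fid for fid, *_ in VCF_INFO_FIELDS} | {"SVTYPE", "END", "NMIPS",
                                                    "MEANRATIO", "IMPRECISE"}
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            row = {"genomic_pos": rec.pos, "ref": rec.ref,
                   "alt": rec.alts[0] if rec.alts else ""}
            for key, val in rec.info.items():
                if key not in known:
                    logger.warning("unknown INFO key %s preserved in memory only", key)
                col = _INFO_TO_TSV.get(key)
                if col is None:
                    continue
                if isinstance(val, str):
                    val = val.replace("_", " ") if col in ("sift", "mtaster") else val
                row[col] = val
            row["in_cis_with_stopgain"] = "CIS" in rec.info
            row["functionally_confirmed"] = "CONF" in rec.info
            row["homozygous"] = "HOM" in rec.info
            rows.append(row)
    df = pd.DataFrame(rows)
    # VCF stores floats as float32; round back to table precision
    for col in ("maf", "read_fraction", "cadd", "phylop", "sai_ag", "sai_al",
                "sai_dg", "sai_dl"):
        if col in df:
            df[col] = df[col].astype(float).round(4)
    return df


def write_cnv_vcf(calls: list[CnvCall], path: str | Path, model: GeneModel,
                  panel, config: PipelineConfig | None = None) -> None:
    """Symbolic SV records (SVTYPE=DEL/DUP) for coverage-based CNV calls."""
    header = _vcf_header(model, config)
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for call in calls:
            rec = vcf.new_record(
                contig=model.contig, start=panel[call.first_mip_index].start - 1,
                stop=panel[call.last_mip_index].end,
                alleles=("N", "<DEL>" if call.type == "deletion" else "<DUP>"))
            rec.info["SVTYPE"] = "DEL" if call.type == "deletion" else "DUP"
            rec.info["NMIPS"] = call.n_mips
            rec.info["MEANRATIO"] = float(call.mean_ratio)
            rec.info["SAMPLE"] = call.sample_id
            rec.info["IMPRECISE"] = True
            vcf.write(rec)


# -- low-coverage report -----------------------------------------------

def write_low_coverage_bed(regions: list[LowCoverageRegion], path: str | Path,
                           panel, contig: str) -> None:
    with open(path, "w") as fh:
        for r in regions:
            start0 = panel[r.first_mip_index].start - 1
            end = panel[r.last_mip_index].end
            name = f"{r.sample_id}|{r.tier}|min={r.min_reads}"
            fh.write(f"{contig}\t{start0}\t{end}\t{name}\n")


def low_coverage_to_frame(regions: list[LowCoverageRegion]) -> pd.DataFrame:
    cols = ["sample_id", "first_mip_id", "last_mip_id", "first_mip_index",
            "last_mip_index", "min_reads", "manual_check", "sanger"]
    return pd.DataFrame([{c: getattr(r, c) for c in cols} for r in regions],
                        columns=cols)
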