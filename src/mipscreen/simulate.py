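"""Synthetic cohort generator: coverage matrices, annotated variant tables
and planted truth for an autosomal-recessive MIP screening panel.

The generator emulates the statistical structure the downstream analysis
assumes, so every stage is testable without external data:

* per-MIP capture efficiency drawn log-normally (shared across samples,
  fixed per panel) to emulate the orders-of-magnitude spread of real MIP
  coverage around a ~1488x mean;
* read counts drawn negative-binomially around
  ``mean_depth x efficiency x copy_state/2`` (het deletion halves the
  expectation, a single-copy gain multiplies by 1.5, homozygous loss
  leaves only a small residual capture background);
* planted variant alleles with annotation fields (population frequency,
  in-silico scores, splice deltas, database status, read fraction) chosen
  to satisfy — or, for labelled decoys, violate — the triage rules;
* a study-mirror cohort of 29 USH2 + 11 arRP cases whose planted genotype
  classes reproduce the published diagnostic yield tiers.

CNV alleles appear only in the coverage matrix, never in the SNV table.
All randomness derives from a single master seed via fixed stream offsets.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .genemodel import GeneModel
from .hgvs import parse_c
from .panel import MipPanel

DEFAULT_MEAN_DEPTH = 1488.0
DEFAULT_DISPERSION = 150.0
DEFAULT_EFFICIENCY_SIGMA = 1.0
#: residual capture of a homozygously deleted target, as a copy fraction
RESIDUAL_CAPTURE = 0.02


# ---------------------------------------------------------------------
# coverage simulation
# ---------------------------------------------------------------------

@dataclass(frozen=True)
class CnvEvent:
    """A planted copy-number event over a run of consecutive probes."""

    sample_id: str
    first_mip_index: int
    n_mips: int
    copy_state: int  # 0 = homozygous loss, 1 = het deletion, 3 = dup
    qpcr_confirmed: bool = False  # orthogonal confirmation, for sub-run-length events
    hgvs_c: str = ""

    def __post_init__(self) -> None:
        if self.n_mips < 1:
            raise ValueError("CNV event must span >= 1 MIP")
        if self.copy_state == 2:
            raise ValueError("copy_state 2 is the diploid reference, not an event")

    @property
    def last_mip_index(self) -> int:
        return self.first_mip_index + self.n_mips - 1

    @property
    def homozygous(self) -> bool:
        return self.copy_state == 0

    @property
    def is_deletion(self) -> bool:
        return self.copy_state < 2


@dataclass
class CoverageSimSpec:
    """Noise model and planted events for one simulated coverage matrix."""

    mean_depth: float = DEFAULT_MEAN_DEPTH
    dispersion: float = DEFAULT_DISPERSION  # NB size parameter; inf = Poisson
    efficiency_sigma: float = DEFAULT_EFFICIENCY_SIGMA
    cnv_events: list[CnvEvent] = field(default_factory=list)
    dropout_mips: list[int] = field(default_factory=list)


def panel_efficiencies(n_mips: int, sigma: float, rng: np.random.Generator) -> np.ndarray:
    """Log-normal per-MIP capture efficiencies with mean 1."""
    if sigma == 0:
        return np.ones(n_mips)
    return rng.lognormal(mean=-sigma ** 2 / 2, sigma=sigma, size=n_mips)


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, size_param: float) -> np.ndarray:
    mu = np.asarray(mu, dtype=float)
    if math.isinf(size_param):
        return rng.poisson(mu)
    p = size_param / (size_param + mu)
    return rng.negative_binomial(size_param, p)


def simulate_coverage(panel: MipPanel, sample_ids: list[str] | int,
                      spec: CoverageSimSpec | None = None,
                      seed: int = 0) -> pd.DataFrame:
    """Simulate a samples x MIPs raw read-count matrix.

    Deterministic for a given seed.  Returns a DataFrame indexed by sample
    id with one column per MIP in panel order.
    """
    spec = spec or CoverageSimSpec()
    if isinstance(sample_ids, int):
        sample_ids = [f"S{i + 1:03d}" for i in range(sample_ids)]
    rng = np.random.default_rng(seed)
    eff = panel_efficiencies(len(panel), spec.efficiency_sigma, rng)

    copy_factor = np.ones((len(sample_ids), len(panel)))
    sample_pos = {s: i for i, s in enumerate(sample_ids)}
    for ev in spec.cnv_events:
        if ev.sample_id not in sample_pos:
            raise ValueError(f"CNV event for unknown sample {ev.sample_id!r}")
        lo, hi = ev.first_mip_index, ev.last_mip_index + 1
        if hi > len(panel):
            raise ValueError("CNV event extends beyond the panel")
        factor = ev.copy_state / 2 if ev.copy_state else RESIDUAL_CAPTURE
        copy_factor[sample_pos[ev.sample_id], lo:hi] = factor

    mu = spec.mean_depth * eff[None, :] * copy_factor
    counts = _nb_draw(rng, mu, spec.dispersion)
    counts[:, [m for m in spec.dropout_mips]] = 0
    return pd.DataFrame(counts, index=pd.Index(sample_ids, name="sample_id"),
                        columns=panel.mip_ids)


# ---------------------------------------------------------------------
# variant catalog (published recurrent alleles + synthetic stand-ins)
# ---------------------------------------------------------------------

def _v(hgvs_c, hgvs_p, consequence, *, maf=float("nan"), gr=float("nan"),
       cadd=float("nan"), phylop=float("nan"), sift="n/a", mtaster="n/a",
       sai=(0.0, 0.0, 0.0, 0.0), db="none", confirmed=False) -> dict:
    return dict(hgvs_c=hgvs_c, hgvs_p=hgvs_p, consequence=consequence, maf=maf,
                grantham=gr, cadd=cadd, phylop=phylop, sift=sift, mtaster=mtaster,
                sai_ag=sai[0], sai_al=sai[1], sai_dg=sai[2], sai_dl=sai[3],
                db_status=db, functionally_confirmed=confirmed)


#: recurrent / known pathogenic alleles of the emulated gene
CATALOG: dict[str, dict] = {c["hgvs_c"]: c for c in [
    _v("c.11864G>A", "p.(Trp3955*)", "stop_gain", maf=0.0004, cadd=44.0,
       phylop=4.4, db="LOVD:pathogenic"),
    _v("c.2299del", "p.(Glu767Serfs*21)", "frameshift", maf=0.0021, cadd=35.0,
       db="LOVD:pathogenic"),
    _v("c.2276G>T", "p.(Cys759Phe)", "missense", maf=0.0028, gr=205, cadd=27.8,
       phylop=5.2, sift="Deleterious", mtaster="Disease causing",
       db="LOVD:pathogenic"),
    _v("c.11683G>T", "p.(Gly3895*)", "stop_gain", cadd=55.0, phylop=5.89),
    _v("c.15286del", "p.(Glu5096Lysfs*6)", "frameshift", cadd=41.0),
    _v("c.3187_3188del", "p.(Gln1063Serfs*15)", "frameshift", maf=0.0002,
       cadd=34.0, db="LOVD:pathogenic"),
    _v("c.9258+1G>A", "", "canonical_splice", maf=0.0001, cadd=34.0,
       sai=(0.02, 0.95, 0.01, 0.62), db="LOVD:pathogenic"),
    _v("c.9371+1G>C", "", "canonical_splice", cadd=33.0,
       sai=(0.0, 0.9, 0.0, 0.85), db="ClinVar:pathogenic"),
    _v("c.11048-2A>G", "", "canonical_splice", maf=0.0001, cadd=33.5,
       sai=(0.8, 0.9, 0.0, 0.0), db="LOVD:pathogenic"),
    _v("c.7595-3C>G", "", "intronic", maf=0.0009, cadd=24.0,
       sai=(0.45, 0.62, 0.0, 0.0), db="LOVD:pathogenic", confirmed=True),
    _v("c.949C>A", "p.(=,Tyr318Cysfs*17)", "synonymous", maf=0.0003, cadd=18.0,
       sai=(0.55, 0.38, 0.0, 0.0), db="LOVD:pathogenic", confirmed=True),
    _v("c.8709C>T", "p.(Arg2894_Asn2906del,=)", "synonymous", cadd=17.0,
       sai=(0.65, 0.4, 0.0, 0.0), confirmed=True),
    # novel missense, submitted to the locus database after classification
    _v("c.9388T>G", "p.(Trp3130Gly)", "missense", gr=184, cadd=25.5, phylop=5.06,
       sift="Deleterious", mtaster="Disease causing", db="LOVD:likely_pathogenic"),
    _v("c.14303A>C", "p.(Tyr4768Ser)", "missense", gr=144, cadd=26.1, phylop=4.17,
       sift="Deleterious", mtaster="Disease causing", db="LOVD:likely_pathogenic"),
    # known pathogenic missense used as pre-screened arRP first alleles
    _v("c.4106C>T", "p.(Ser1369Leu)", "missense", maf=0.0005, gr=145, cadd=26.0,
       phylop=3.5, sift="Deleterious", mtaster="Disease causing",
       db="LOVD:likely_pathogenic"),
    _v("c.9815C>T", "p.(Pro3272Leu)", "missense", maf=0.0008, gr=98, cadd=29.0,
       phylop=5.0, sift="Deleterious", mtaster="Disease causing",
       db="LOVD:pathogenic"),
    _v("c.10073G>A", "p.(Cys3358Tyr)", "missense", maf=0.0001, gr=194, cadd=28.0,
       phylop=4.8, sift="Deleterious", mtaster="Disease causing",
       db="LOVD:pathogenic"),
    # synthetic stand-ins: missense VUS meeting >=4/5 in-silico criteria
    _v("c.5000G>A", "p.(Gly1667Asp)", "missense", gr=94, cadd=24.1, phylop=3.9,
       sift="Deleterious", mtaster="Disease causing"),
    _v("c.6800T>C", "p.(Leu2267Pro)", "missense", gr=98, cadd=23.2, phylop=3.1,
       sift="Deleterious", mtaster="Disease causing"),
    _v("c.12400C>T", "p.(Arg4134Trp)", "missense", gr=101, cadd=28.0, phylop=4.4,
       sift="Deleterious", mtaster="Disease causing"),
    # worked-example variants exercising the keep/drop boundary rules
    _v("c.7067A>G", "p.(Asn2356Ser)", "missense", maf=0.001, gr=46, cadd=22.0,
       phylop=2.9, sift="Deleterious", mtaster="Disease causing",
       db="ClinVar:likely_pathogenic"),
    _v("c.12575G>A", "p.(Arg4192His)", "missense", maf=0.004, gr=29, cadd=21.0,
       phylop=1.2, sift="Tolerated", mtaster="Polymorphism",
       db="ClinVar:benign"),
    _v("c.11389+14del", "", "intronic", maf=0.003, db="LOVD:benign"),
    _v("c.687C>A", "p.(Gly229=)", "synonymous", maf=0.002,
       db="ClinVar:likely_benign"),
]}

#: catalog alleles whose triage tier is pathogenic / likely pathogenic
PLP_ALLELES = [h for h, c in CATALOG.items()
               if c["consequence"] in ("stop_gain", "frameshift", "canonical_splice")
               or "pathogenic" in c["db_status"]
               or c["functionally_confirmed"]]
PLP_ALLELES = [h for h in PLP_ALLELES if "benign" not in CATALOG[h]["db_status"]]
QUALIFYING_VUS = ["c.5000G>A", "c.6800T>C", "c.12400C>T"]


# ---------------------------------------------------------------------
# planted truth containers
# ---------------------------------------------------------------------

@dataclass
class PlantedVariant:
    sample_id: str
    hgvs_c: str
    classification: str  # pathogenic | likely_pathogenic | qualifying_VUS | decoy_*
    homozygous: bool = False
    expected_kept: bool = True
    expected_drop_reason: str = "none"


@dataclass
class PlantedTruth:
    """Ground truth for one simulated cohort."""

    variants: list[PlantedVariant]
    cnv_events: list[CnvEvent]
    manifest: pd.DataFrame  # sample_id, phenotype, prescreened_allele, external_solution

    def to_json(self, path: str | Path) -> None:
        payload = {
            "variants": [asdict(v) for v in self.variants],
            "cnv_events": [asdict(e) for e in self.cnv_events],
            "manifest": self.manifest.to_dict(orient="records"),
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @property
    def cnv_flags(self) -> pd.DataFrame:
        """Wet-lab style flags per planted CNV (confirmation, zygosity)."""
        rows = [{"sample_id": e.sample_id, "first_mip": e.first_mip_index,
                 "last_mip": e.last_mip_index,
                 "qpcr_confirmed": e.qpcr_confirmed, "homozygous": e.homozygous}
                for e in self.cnv_events]
        cols = ["sample_id", "first_mip", "last_mip", "qpcr_confirmed", "homozygous"]
        return pd.DataFrame(rows, columns=cols)


@dataclass
class CohortSpec:
    """Cohort composition: phenotype counts and genotype-class mix."""

    n_ush2: int = 29
    n_arrp: int = 11
    genotype_mix: dict[str, float] = field(default_factory=lambda: {
        "biallelic_PLP": 0.725, "PLP_plus_VUS": 0.075,
        "monoallelic": 0.175, "none": 0.025})
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_ush2 < 0 or self.n_arrp < 0:
            raise ValueError("cohort counts must be non-negative")
        total = sum(self.genotype_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"genotype mix proportions sum to {total}, not 1")


# ---------------------------------------------------------------------
# variant table construction
# ---------------------------------------------------------------------

_TABLE_COLUMNS = [
    "sample_id", "hgvs_c", "hgvs_p", "consequence", "genomic_pos", "ref", "alt",
    "maf", "read_fraction", "grantham", "cadd", "phylop", "sift", "mtaster",
    "sai_ag", "sai_al", "sai_dg", "sai_dl", "db_status", "in_cis_with_stopgain",
    "functionally_confirmed", "homozygous", "probe_support",
]


def _support_string(panel: MipPanel, genomic_pos: int,
                    supported_ids: set[str] | None = None) -> str:
    """Encode per-overlapping-probe variant support as 'MIP0001:1|...'.

    ``supported_ids=None`` means the variant is seen in every probe."""
    parts = []
    for p in panel.probes_overlapping(genomic_pos):
        seen = 1 if supported_ids is None or p.mip_id in supported_ids else 0
        parts.append(f"{p.mip_id}:{seen}")
    return "|".join(parts)


def _variant_row(sample_id: str, hgvs_c: str, model: GeneModel, panel: MipPanel,
                 rng: np.random.Generator, *, homozygous: bool = False,
                 in_cis_with_stopgain: bool = False,
                 read_fraction: float | None = None) -> dict:
    cat = CATALOG[hgvs_c]
    v = parse_c(hgvs_c)
    gpos = model.coding_to_genomic(v.start)
    if read_fraction is None:
        low_rf = {"c.7067A>G": 0.10, "c.11389+14del": 0.08, "c.687C>A": 0.11}
        if hgvs_c in low_rf:
            read_fraction = low_rf[hgvs_c]
        elif homozygous:
            read_fraction = float(np.clip(rng.normal(0.97, 0.015), 0.9, 1.0))
        else:
            read_fraction = float(np.clip(rng.normal(0.5, 0.05), 0.3, 0.7))
    row = dict(cat)
    row.update(sample_id=sample_id, genomic_pos=gpos,
               ref=v.ref if v.edit == "substitution" else "N",
               alt=v.alt if v.edit == "substitution" else "",
               read_fraction=round(read_fraction, 3),
               in_cis_with_stopgain=in_cis_with_stopgain, homozygous=homozygous,
               probe_support=_support_string(panel, gpos))
    return row


def inject_annotation_noise(table: pd.DataFrame, benign_fraction: float,
                            seed: int, panel: MipPanel, model: GeneModel,
                            truth: PlantedTruth | None = None) -> pd.DataFrame:
    """Add labelled decoy variants that the triage cascade must remove.

    ``benign_fraction`` scales the number of decoys relative to the number
    of planted rows (0 leaves the table unchanged).  Decoy classes cycle
    through: common variants (MAF > 1%), low read-fraction artifacts
    without database support, probe-edge artifacts unsupported in the
    overlapping probe, and database-benign variants.  Decoys are appended
    to ``truth.variants`` with their expected drop reason.
    """
    n_decoys = int(round(benign_fraction * len(table)))
    if n_decoys == 0:
        return table.copy()
    rng = np.random.default_rng(seed)
    samples = sorted(table["sample_id"].unique())
    planted_pos = set(table["genomic_pos"])
    classes = ["maf", "read_fraction", "edge_artifact", "benign_db"]
    bases = "ACGT"
    rows = []
    made = 0
    while made < n_decoys:
        cls = classes[made % len(classes)]
        sample = samples[int(rng.integers(len(samples)))]
        if cls == "edge_artifact":
            probe = panel.probes[int(rng.integers(len(panel)))]
            gpos = probe.end
            cpos = model.genomic_to_coding(gpos)
            if 1 <= abs(cpos.offset) <= 2 or gpos in planted_pos:
                continue  # avoid canonical-splice decoys / collisions
            support = _support_string(panel, gpos, supported_ids={probe.mip_id})
        else:
            base = int(rng.integers(1, model.coding_length + 1))
            e = model.exon_for_coding_base(base)
            gpos = e.genomic_start + (base - e.c_start)
            cpos = model.genomic_to_coding(gpos)
            if gpos in planted_pos:
                continue
            support = _support_string(panel, gpos)
        ref, alt = rng.choice(list(bases), size=2, replace=False)
        off = ""
        if cpos.offset:
            off = f"{cpos.offset:+d}"
        hgvs_c = f"c.{cpos.base}{off}{ref}>{alt}"
        consequence = "intronic" if cpos.offset else "synonymous"
        row = _v(hgvs_c, "", consequence, cadd=float(rng.uniform(0, 8)),
                 phylop=float(rng.uniform(-1, 1.5)))
        row.update(sample_id=sample, genomic_pos=gpos, ref=ref, alt=alt,
                   read_fraction=round(float(rng.uniform(0.3, 0.6)), 3),
                   in_cis_with_stopgain=False, homozygous=False,
                   probe_support=support)
        if cls == "maf":
            row["maf"] = round(float(rng.uniform(0.02, 0.3)), 4)
        elif cls == "read_fraction":
            row["read_fraction"] = round(float(rng.uniform(0.02, 0.12)), 3)
        elif cls == "benign_db":
            row["maf"] = round(float(rng.uniform(0.0005, 0.009)), 4)
            row["db_status"] = "ClinVar:benign"
        if truth is not None:
            truth.variants.append(PlantedVariant(
                sample_id=sample, hgvs_c=hgvs_c, classification=f"decoy_{cls}",
                expected_kept=False, expected_drop_reason=cls))
        rows.append(row)
        made += 1
    out = pd.concat([table, pd.DataFrame(rows)], ignore_index=True)
    return out[_TABLE_COLUMNS]


# ---------------------------------------------------------------------
# cohort assembly
# ---------------------------------------------------------------------

def _probe_range(panel: MipPanel, g_start: int, g_end: int) -> tuple[int, int]:
    probes = panel.probes_within(g_start, g_end)
    if not probes:
        raise ValueError("no probes inside the requested interval")
    return probes[0].panel_index, probes[-1].panel_index


def mirror_cnv_regions(panel: MipPanel, model: GeneModel) -> dict[str, tuple[int, int]]:
    """Panel-index ranges of the four fixture CNVs, from their breakpoints."""
    g = model.coding_to_genomic

    def rng_of(c_from, c_to):
        return _probe_range(panel, g(parse_c(c_from).start), g(parse_c(c_to).start))

    ex43_first = model.exon(43).genomic_start - 250
    ex43_last = model.exon(43).genomic_end + 250
    return {
        # known breakpoints: probes fully inside the deleted segment
        "ex10_11": rng_of("c.1644+10004A>C", "c.1972-12164A>C"),
        "ex22_24": rng_of("c.4627+25435A>C", "c.4987+660A>C"),
        "ex38_56": rng_of("c.7121-8313A>C", "c.11048-962A>C"),
        # unknown breakpoints: probes over exon 43 +/- a short margin
        "ex43": _probe_range(panel, ex43_first, ex43_last),
    }


_MIRROR_CNV_HGVS = {
    "ex10_11": "c.1644+10004_1972-12164del",
    "ex22_24": "c.4627+25435_4987+660del",
    "ex38_56": "c.7121-8313_11048-962delins12",
    "ex43": "c.8559-?_8681+?del",
}


def _mirror_assignments() -> list[dict]:
    """Fixed per-sample genotype plan reproducing the published yield tiers.

    29 USH2 + 11 arRP; 29 biallelic P/LP, 3 P/LP + qualifying VUS,
    7 monoallelic, 1 with no allele in the target gene (externally solved).
    """
    plan: list[dict] = []

    def add(sid, pheno, snvs=(), hom_snvs=(), cnv=None, cnv_copy=1,
            prescreened="", external=False, extras=()):
        plan.append(dict(sample_id=sid, phenotype=pheno, snvs=list(snvs),
                         hom_snvs=list(hom_snvs), cnv=cnv, cnv_copy=cnv_copy,
                         prescreened=prescreened, external=external,
                         extras=list(extras)))

    # recurrent multi-exon deletion: five carriers, one homozygous
    add("U01", "USH2", cnv="ex38_56", cnv_copy=0)
    add("U02", "USH2", snvs=["c.2299del"], cnv="ex38_56")
    add("U03", "USH2", snvs=["c.9371+1G>C"], cnv="ex38_56",
        extras=["c.11389+14del"])
    add("U04", "USH2", snvs=["c.11048-2A>G"], cnv="ex38_56")
    add("U05", "USH2", snvs=["c.2276G>T"], cnv="ex38_56", extras=["c.687C>A"])
    # single-exon / few-exon deletions confirmed by qPCR
    add("U06", "USH2", snvs=["c.11864G>A"], cnv="ex43")
    add("U07", "USH2", snvs=["c.2299del"], cnv="ex10_11")
    add("U08", "USH2", snvs=["c.9258+1G>A"], cnv="ex22_24")
    # splice-confirmed synonymous allele in trans with a frameshift
    add("U09", "USH2", snvs=["c.8709C>T", "c.3187_3188del"])
    # fully pre-solved case also carrying a low-read-fraction known allele
    add("U10", "USH2", snvs=["c.9258+1G>A", "c.11864G>A"],
        extras=["c.7067A>G", "c.12575G>A"])
    # recurrent stop-gain first allele
    second = ["c.2299del", "c.2276G>T", "c.7595-3C>G", "c.949C>A",
              "c.9371+1G>C", "c.11683G>T", "c.15286del", "c.3187_3188del",
              "c.11048-2A>G"]
    for i, partner in enumerate(second, start=11):
        add(f"U{i:02d}", "USH2", snvs=["c.11864G>A", partner])
    add("U20", "USH2", snvs=["c.9388T>G", "c.11683G>T"])
    add("U21", "USH2", snvs=["c.14303A>C", "c.15286del"])
    add("U22", "USH2", hom_snvs=["c.2299del"])
    add("U23", "USH2", snvs=["c.2276G>T", "c.9815C>T"])
    add("U24", "USH2", snvs=["c.10073G>A", "c.4106C>T"])
    add("U25", "USH2", snvs=["c.9258+1G>A", "c.5000G>A"])
    add("U26", "USH2", snvs=["c.2299del", "c.6800T>C"])
    add("U27", "USH2", snvs=["c.11864G>A"])
    add("U28", "USH2", snvs=["c.2276G>T"])
    add("U29", "USH2", external=True)  # solved outside the target gene

    # arRP: pre-screened monoallelic inclusions
    pre_stop = ["c.11864G>A", "c.2299del", "c.3187_3188del", "c.15286del",
                "c.11683G>T"]
    partner = ["c.9815C>T", "c.9258+1G>A", "c.2276G>T", "c.10073G>A",
               "c.9371+1G>C"]
    for i, (p1, p2) in enumerate(zip(pre_stop, partner), start=1):
        add(f"R{i:02d}", "arRP", snvs=[p1, p2], prescreened=p1)
    add("R06", "arRP", snvs=["c.2276G>T", "c.12400C>T"], prescreened="c.2276G>T")
    for i, pre in enumerate(["c.4106C>T", "c.9815C>T", "c.10073G>A",
                             "c.2276G>T", "c.4106C>T"], start=7):
        add(f"R{i:02d}", "arRP", snvs=[pre], prescreened=pre)
    return plan


_TIER_OF = {}
for _h, _c in CATALOG.items():
    if "benign" in _c["db_status"]:
        _TIER_OF[_h] = "excluded"
    elif _c["consequence"] in ("stop_gain", "frameshift", "canonical_splice"):
        _TIER_OF[_h] = "pathogenic"
    elif _c["db_status"].endswith("likely_pathogenic"):
        _TIER_OF[_h] = "likely_pathogenic"
    elif _c["db_status"].endswith("pathogenic") or _c["functionally_confirmed"]:
        _TIER_OF[_h] = "pathogenic"
    else:
        _TIER_OF[_h] = "qualifying_VUS"


def mirror_cohort(panel: MipPanel, model: GeneModel, seed: int = 0,
                        benign_fraction: float = 1.0,
                        sim_spec: CoverageSimSpec | None = None,
                        ) -> tuple[PlantedTruth, pd.DataFrame, pd.DataFrame]:
    """Build the 40-case mirror cohort: truth, variant table, coverage.

    Returns (truth, variants, coverage); coverage planted with the four
    CNVs (9 alleles), variant table with all SNV alleles plus decoys.
    """
    rng = np.random.default_rng(seed)
    regions = mirror_cnv_regions(panel, model)
    plan = _mirror_assignments()

    events: list[CnvEvent] = []
    truth_variants: list[PlantedVariant] = []
    rows: list[dict] = []
    manifest_rows: list[dict] = []
    for entry in plan:
        sid = entry["sample_id"]
        manifest_rows.append(dict(sample_id=sid, phenotype=entry["phenotype"],
                                  prescreened_allele=entry["prescreened"],
                                  external_solution=entry["external"]))
        for h in entry["snvs"]:
            rows.append(_variant_row(sid, h, model, panel, rng))
            truth_variants.append(PlantedVariant(sid, h, _TIER_OF[h]))
        for h in entry["hom_snvs"]:
            rows.append(_variant_row(sid, h, model, panel, rng, homozygous=True))
            truth_variants.append(PlantedVariant(sid, h, _TIER_OF[h], homozygous=True))
        for h in entry["extras"]:
            rows.append(_variant_row(sid, h, model, panel, rng))
            if "benign" in CATALOG[h]["db_status"]:
                truth_variants.append(PlantedVariant(
                    sid, h, "decoy_benign_db", expected_kept=False,
                    expected_drop_reason="benign_db"))
            else:
                truth_variants.append(PlantedVariant(sid, h, _TIER_OF[h]))
        if entry["cnv"]:
            first, last = regions[entry["cnv"]]
            n = last - first + 1
            events.append(CnvEvent(sample_id=sid, first_mip_index=first,
                                   n_mips=n, copy_state=entry["cnv_copy"],
                                   qpcr_confirmed=n < 7,
                                   hgvs_c=_MIRROR_CNV_HGVS[entry["cnv"]]))

    manifest = pd.DataFrame(manifest_rows)
    truth = PlantedTruth(variants=truth_variants, cnv_events=events,
                         manifest=manifest)
    table = pd.DataFrame(rows)[_TABLE_COLUMNS]
    table = inject_annotation_noise(table, benign_fraction, seed + 1,
                                    panel, model, truth)

    spec = sim_spec or CoverageSimSpec()
    spec.cnv_events = events
    if not spec.dropout_mips:
        # a couple of structurally failed probes, away from planted events
        in_event = {i for e in events
                    for i in range(e.first_mip_index, e.last_mip_index + 1)}
        candidates = [i for i in range(len(panel)) if i not in in_event]
        spec.dropout_mips = sorted(rng.choice(candidates, size=2, replace=False).tolist())
    coverage = simulate_coverage(panel, list(manifest["sample_id"]), spec,
                                 seed=seed + 2)
    return truth, table, coverage


#: event sizes for the CNV parameter-recovery study: multi-exon deletions
#: (auto-call tier) and single-/few-exon deletions (qPCR follow-up tier;
#: at the 90-nt tiling step a typical exon spans >= 3 probes — the 2-probe
#: minimum, e.g. a 123-nt exon, is exercised by the study-mirror fixture)
LARGE_EVENT_SIZES = (8, 10, 12, 15, 20)
SMALL_EVENT_SIZES = (3, 4, 5, 6)


def plant_random_events(panel: MipPanel, sample_ids: list[str],
                        rng: np.random.Generator, n_large: int = 2,
                        n_small: int = 1) -> list[CnvEvent]:
    """Plant non-overlapping deletion events on distinct samples.

    Large events alternate heterozygous/homozygous; small (sub-run-length)
    events are heterozygous.  Positions are uniform over the panel.
    """
    chosen = rng.choice(len(sample_ids), size=n_large + n_small, replace=False)
    events: list[CnvEvent] = []
    for k in range(n_large):
        size = int(rng.choice(LARGE_EVENT_SIZES))
        first = int(rng.integers(0, len(panel) - size + 1))
        events.append(CnvEvent(sample_id=sample_ids[chosen[k]],
                               first_mip_index=first, n_mips=size,
                               copy_state=0 if k % 2 else 1))
    for k in range(n_large, n_large + n_small):
        size = int(rng.choice(SMALL_EVENT_SIZES))
        first = int(rng.integers(0, len(panel) - size + 1))
        events.append(CnvEvent(sample_id=sample_ids[chosen[k]],
                               first_mip_index=first, n_mips=size,
                               copy_state=1))
    return events


def simulate_cohort(spec: CohortSpec, panel: MipPanel, model: GeneModel,
                    seed: int | None = None, benign_fraction: float = 0.0,
                    ) -> tuple[PlantedTruth, pd.DataFrame, pd.DataFrame]:
    """Simulate a cohort with genotype classes drawn from ``genotype_mix``.

    Classes are allocated by largest remainder so the realized counts match
    the proportions as closely as integers allow; alleles are drawn from
    the packaged catalog.  CNV alleles are not planted on this generic
    path (see :func:`mirror_cohort` for the CNV-bearing fixture).
    """
    seed = spec.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    n = spec.n_ush2 + spec.n_arrp
    sample_ids = [f"U{i + 1:02d}" for i in range(spec.n_ush2)] + \
                 [f"R{i + 1:02d}" for i in range(spec.n_arrp)]
    phenos = ["USH2"] * spec.n_ush2 + ["arRP"] * spec.n_arrp

    classes = list(spec.genotype_mix)
    exact = np.array([spec.genotype_mix[c] * n for c in classes])
    counts = np.floor(exact).astype(int)
    rem = exact - counts
    for i in np.argsort(-rem)[: n - counts.sum()]:
        counts[i] += 1
    assignment = [c for c, k in zip(classes, counts) for _ in range(k)]
    rng.shuffle(assignment)

    plp = [h for h in PLP_ALLELES if h not in ("c.7067A>G",)]
    rows: list[dict] = []
    truth_variants: list[PlantedVariant] = []
    manifest_rows: list[dict] = []
    for sid, pheno, cls in zip(sample_ids, phenos, assignment):
        manifest_rows.append(dict(sample_id=sid, phenotype=pheno,
                                  prescreened_allele="",
                                  external_solution=cls == "none"))
        alleles: list[str] = []
        if cls == "biallelic_PLP":
            alleles = list(rng.choice(plp, size=2, replace=False))
        elif cls == "PLP_plus_VUS":
            alleles = [str(rng.choice(plp)), str(rng.choice(QUALIFYING_VUS))]
        elif cls == "monoallelic":
            alleles = [str(rng.choice(plp))]
        for h in alleles:
            rows.append(_variant_row(sid, h, model, panel, rng))
            truth_variants.append(PlantedVariant(sid, h, _TIER_OF[h]))

    manifest = pd.DataFrame(manifest_rows)
    truth = PlantedTruth(variants=truth_variants, cnv_events=[], manifest=manifest)
    table = pd.DataFrame(rows, columns=_TABLE_COLUMNS)
    table = inject_annotation_noise(table, benign_fraction, seed + 1,
                                    panel, model, truth)
    coverage = simulate_coverage(panel, sample_ids, CoverageSimSpec(), seed=seed + 2)
    return truth, table, coverage
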