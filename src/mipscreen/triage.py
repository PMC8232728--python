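"""SNV filter-and-classify cascade for an annotated panel variant table.

The cascade applies, in any order (each step is a pure predicate):

* a population-frequency filter (keep MAF <= 1%; absent = novel = keep);
* a read-fraction filter (variants under 15% of reads are kept only when
  already reported in a locus/clinical database);
* a probe-edge artifact filter (a variant at the last nucleotide of a MIP
  target that no overlapping MIP supports is a known capture artifact);

then scores missense variants against five in-silico criteria
(Grantham >= 80, CADD_PHRED >= 15, PhyloP >= 2.7, SIFT "Deleterious",
MutationTaster "Disease causing"; >= 4 of 5 to qualify), gates variants
into the splice-assay candidate list (>= 2 of the 4 splice delta scores
>= 0.2, excluding stop-gains, canonical splice variants and variants in
cis with a stop-gain), and assigns an operational evidence tier.

The tiers are the screening study's working categories, not a formal
ACMG classification; do not use them for clinical reporting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .hgvs import CodingVariant, is_canonical_splice, parse_c
from .panel import MipPanel

MAX_MAF = 0.01
MIN_READ_FRACTION = 0.15
SPLICE_DELTA = 0.2
SPLICE_MIN_HITS = 2
MISSENSE_MIN_CRITERIA = 4
GRANTHAM_MIN_SCORE = 80
CADD_MIN = 15.0
PHYLOP_MIN = 2.7

CONSEQUENCES = ("stop_gain", "frameshift", "canonical_splice", "missense",
                "synonymous", "intronic", "inframe_indel")


@dataclass
class VariantRecord:
    """One called SNV/indel with its annotations, as consumed by triage."""

    sample_id: str
    hgvs_c: CodingVariant
    consequence: str
    hgvs_p: str = ""
    genomic_pos: int | None = None
    maf: float = float("nan")  # NaN = absent from the population database
    read_fraction: float = 0.5
    grantham: float = float("nan")
    cadd: float = float("nan")
    phylop: float = float("nan")
    sift: str = "n/a"
    mtaster: str = "n/a"
    spliceai: tuple[float, float, float, float] = (0.0, 0.0, 0.0, 0.0)
    db_status: str = "none"  # none | LOVD:<label> | ClinVar:<label>
    in_cis_with_stopgain: bool = False
    functionally_confirmed: bool = False
    homozygous: bool = False
    probe_support: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if isinstance(self.hgvs_c, str):
            self.hgvs_c = parse_c(self.hgvs_c)
        if self.consequence not in CONSEQUENCES:
            raise ValueError(f"unknown consequence {self.consequence!r}")
        if not np.isnan(self.maf) and not 0 <= self.maf <= 1:
            raise ValueError("MAF must be a fraction")
        if not 0 <= self.read_fraction <= 1:
            raise ValueError("read fraction must be a fraction")
        if any(not 0 <= d <= 1 for d in self.spliceai):
            raise ValueError("splice delta scores must be in [0, 1]")
        if (self.consequence == "canonical_splice") != is_canonical_splice(self.hgvs_c):
            raise ValueError(
                f"consequence {self.consequence!r} inconsistent with "
                f"{self.hgvs_c.format()} (canonical = intron offset +/-1 or 2)")

    @property
    def db_label(self) -> str:
        return self.db_status.split(":", 1)[1] if ":" in self.db_status else "none"

    @property
    def in_database(self) -> bool:
        return self.db_status not in ("", "none")


# -- pure filter predicates (True = keep) ------------------------------

def filter_af(v: VariantRecord, max_maf: float = MAX_MAF) -> bool:
    """Keep variants at or below the population-frequency ceiling.

    A missing frequency means the variant is absent from the database
    (novel) and is kept."""
    return bool(np.isnan(v.maf) or v.maf <= max_maf)


def filter_read_fraction(v: VariantRecord, min_rf: float = MIN_READ_FRACTION) -> bool:
    """Keep low read-fraction variants only with prior database evidence."""
    return bool(v.read_fraction >= min_rf or v.in_database)


def filter_edge_artifact(v: VariantRecord, panel: MipPanel,
                         support: dict[str, bool] | None = None) -> bool:
    """Drop probe-terminal variants unsupported by any overlapping probe.

    ``support`` maps mip_id -> whether the variant is seen in that probe's
    reads (defaults to the record's own ``probe_support``).  A variant not
    at any probe's last target nucleotide is kept unconditionally.
    """
    if v.genomic_pos is None:
        return True
    support = v.probe_support if support is None else support
    terminals = panel.is_probe_terminal(v.genomic_pos)
    if not terminals:
        return True
    terminal_ids = {p.mip_id for p in terminals}
    others = [p for p in panel.probes_overlapping(v.genomic_pos)
              if p.mip_id not in terminal_ids]
    return any(support.get(p.mip_id, False) for p in others)


def missense_criteria(v: VariantRecord,
                      min_criteria: int = MISSENSE_MIN_CRITERIA) -> tuple[int, bool]:
    """Count the five in-silico pathogenicity criteria a missense meets.

    A missing score counts as not satisfied.  Returns (count, count >= 4).
    """
    if v.consequence != "missense":
        raise ValueError("missense criteria apply to missense variants only")
    count = sum([
        not np.isnan(v.grantham) and v.grantham >= GRANTHAM_MIN_SCORE,
        not np.isnan(v.cadd) and v.cadd >= CADD_MIN,
        not np.isnan(v.phylop) and v.phylop >= PHYLOP_MIN,
        v.sift == "Deleterious",
        v.mtaster == "Disease causing",
    ])
    return count, count >= min_criteria


def splice_assay_gate(v: VariantRecord, min_delta: float = SPLICE_DELTA,
                      min_hits: int = SPLICE_MIN_HITS) -> bool:
    """Should this variant be considered for a minigene splice assay?

    Requires >= ``min_hits`` of the four splice delta scores (acceptor
    gain/loss, donor gain/loss) at or above ``min_delta``.  Stop-gain
    variants, canonical splice-site variants and variants in cis with a
    stop-gain are excluded regardless of score.
    """
    if v.consequence in ("stop_gain", "canonical_splice") or v.in_cis_with_stopgain:
        return False
    return sum(d >= min_delta for d in v.spliceai) >= min_hits


def splice_near_miss(v: VariantRecord, min_delta: float = SPLICE_DELTA) -> bool:
    """Exactly one delta at/above threshold: flagged for manual review."""
    return sum(d >= min_delta for d in v.spliceai) == 1


# -- tier assignment ---------------------------------------------------

TIERS = ("pathogenic", "likely_pathogenic", "qualifying_VUS", "VUS", "excluded")


@dataclass
class TriageDecision:
    """Full decision trail for one variant."""

    variant: VariantRecord
    kept: bool
    drop_reason: str  # maf | read_fraction | edge_artifact | benign_db | none
    missense_criteria_met: int | None
    splice_assay_candidate: bool
    tier: str

    def __post_init__(self) -> None:
        if not self.kept and self.tier != "excluded":
            raise ValueError("dropped variants must carry tier 'excluded'")


def assign_tier(v: VariantRecord, panel: MipPanel | None = None, *,
                max_maf: float = MAX_MAF, min_rf: float = MIN_READ_FRACTION,
                min_delta: float = SPLICE_DELTA, min_hits: int = SPLICE_MIN_HITS,
                min_criteria: int = MISSENSE_MIN_CRITERIA) -> TriageDecision:
    """Run the full cascade on one variant and return its decision trail."""
    drop_reason = "none"
    if not filter_af(v, max_maf):
        drop_reason = "maf"
    elif not filter_read_fraction(v, min_rf):
        drop_reason = "read_fraction"
    elif panel is not None and not filter_edge_artifact(v, panel):
        drop_reason = "edge_artifact"
    elif v.db_label in ("benign", "likely_benign"):
        drop_reason = "benign_db"

    criteria = None
    if v.consequence == "missense":
        criteria, _ = missense_criteria(v, min_criteria)
    candidate = splice_assay_gate(v, min_delta, min_hits)

    if drop_reason != "none":
        return TriageDecision(v, kept=False, drop_reason=drop_reason,
                              missense_criteria_met=criteria,
                              splice_assay_candidate=False, tier="excluded")

    if v.consequence in ("stop_gain", "frameshift", "canonical_splice"):
        tier = "pathogenic"
    elif v.db_label == "pathogenic":
        tier = "pathogenic"
    elif v.db_label == "likely_pathogenic":
        tier = "likely_pathogenic"
    elif candidate and v.functionally_confirmed:
        # splice effect demonstrated in a functional assay
        tier = "pathogenic"
    elif v.consequence == "missense" and criteria is not None and criteria >= min_criteria:
        tier = "qualifying_VUS"
    else:
        tier = "VUS"
    return TriageDecision(v, kept=True, drop_reason="none",
                          missense_criteria_met=criteria,
                          splice_assay_candidate=candidate, tier=tier)


# -- table-level driver ------------------------------------------------

def _parse_support(s: str) -> dict[str, bool]:
    if not s or pd.isna(s):
        return {}
    out = {}
    for part in str(s).replace(";", "|").split("|"):
        mip, seen = part.split(":")
        out[mip] = seen == "1"
    return out


def record_from_row(row: pd.Series | dict) -> VariantRecord:
    """Build a VariantRecord from one row of the on-disk variant table."""
    get = row.get

    def _f(key):
        val = get(key)
        return float("nan") if val in (None, "", "-") or pd.isna(val) else float(val)

    return VariantRecord(
        sample_id=str(get("sample_id")), hgvs_c=str(get("hgvs_c")),
        hgvs_p=str(get("hgvs_p") or ""), consequence=str(get("consequence")),
        genomic_pos=None if pd.isna(get("genomic_pos")) else int(get("genomic_pos")),
        maf=_f("maf"), read_fraction=float(get("read_fraction")),
        grantham=_f("grantham"), cadd=_f("cadd"), phylop=_f("phylop"),
        sift=str(get("sift") or "n/a"), mtaster=str(get("mtaster") or "n/a"),
        spliceai=(_f("sai_ag"), _f("sai_al"), _f("sai_dg"), _f("sai_dl")),
        db_status=str(get("db_status") or "none"),
        in_cis_with_stopgain=bool(get("in_cis_with_stopgain")),
        functionally_confirmed=bool(get("functionally_confirmed")),
        homozygous=bool(get("homozygous")),
        probe_support=_parse_support(get("probe_support")),
    )


def triage_table(table: pd.DataFrame, panel: MipPanel | None = None,
                 **thresholds) -> pd.DataFrame:
    """Triage every row of an annotated variant table.

    Returns the decision table (one row per input variant) with the full
    decision trail appended: kept, drop_reason, missense_criteria_met,
    splice_assay_candidate, splice_near_miss, tier.
    """
    records = [record_from_row(row) for _, row in table.iterrows()]
    decisions = [assign_tier(v, panel, **thresholds) for v in records]
    out = table.copy().reset_index(drop=True)
    out["kept"] = [d.kept for d in decisions]
    out["drop_reason"] = [d.drop_reason for d in decisions]
    out["missense_criteria_met"] = [d.missense_criteria_met for d in decisions]
    out["splice_assay_candidate"] = [d.splice_assay_candidate for d in decisions]
    out["splice_near_miss"] = [splice_near_miss(v) for v in records]
    out["tier"] = [d.tier for d in decisions]
    return out


def funnel_counts(decisions: pd.DataFrame) -> dict[str, int]:
    """Per-stage variant counts (the screening funnel, for logging)."""
    uniq = decisions.drop_duplicates(subset=["hgvs_c"])
    return {
        "total": int(len(decisions)),
        "unique": int(len(uniq)),
        "dropped_maf": int((decisions["drop_reason"] == "maf").sum()),
        "dropped_read_fraction": int((decisions["drop_reason"] == "read_fraction").sum()),
        "dropped_edge_artifact": int((decisions["drop_reason"] == "edge_artifact").sum()),
        "dropped_benign_db": int((decisions["drop_reason"] == "benign_db").sum()),
        "kept": int(decisions["kept"].sum()),
        "splice_assay_candidates": int(decisions["splice_assay_candidate"].sum()),
    }
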