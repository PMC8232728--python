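"""Per-case allele combination and cohort diagnostic-yield summary.

A case is *solved* when two qualifying alleles are identified in the
screened gene: either two pathogenic / likely-pathogenic (P/LP) alleles
(``solved_PLP``) or one P/LP allele plus a missense VUS meeting the
in-silico criteria (``solved_with_VUS``).  Cases with a single P/LP
allele are ``monoallelic``; the rest are ``unsolved``.  Unsolved and
monoallelic cases are referred for whole-genome sequencing unless a
parallel effort explained them outside the target gene.

Alleles are assumed in trans unless flagged otherwise; a homozygous
allele counts twice only when an explicit homozygosity flag is set
(read depth alone cannot phase).  CNV alleles enter from coverage-based
calls: auto-called runs directly, qPCR-follow-up runs only with an
orthogonal confirmation flag.  Out-of-frame CNVs are tiered pathogenic,
in-frame CNVs likely-pathogenic (a structure-based upgrade to pathogenic
is a manual flag).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .cnv import CnvCall

PLP_TIERS = ("pathogenic", "likely_pathogenic")
STATUSES = ("solved_PLP", "solved_with_VUS", "monoallelic", "unsolved")


@dataclass
class Allele:
    """One qualifying allele of a case (SNV or CNV)."""

    description: str  # HGVS or CNV exon span
    tier: str
    is_cnv: bool = False
    homozygous: bool = False

    @property
    def count(self) -> int:
        return 2 if self.homozygous else 1


@dataclass
class CaseGenotype:
    sample_id: str
    phenotype: str  # USH2 | arRP
    alleles: list[Allele] = field(default_factory=list)
    prescreened_allele: str = ""
    external_solution: bool = False

    def __post_init__(self) -> None:
        # deduplicate by description (pre-screened alleles re-detected by
        # the panel must not count twice)
        seen: dict[str, Allele] = {}
        for a in self.alleles:
            seen.setdefault(a.description, a)
        self.alleles = list(seen.values())


@dataclass
class CaseResolution:
    sample_id: str
    phenotype: str
    status: str
    n_plp_alleles: int
    n_qualifying_vus: int
    wgs_referral: bool
    alleles: list[Allele] = field(default_factory=list)


def resolve_case(g: CaseGenotype) -> CaseResolution:
    """Combine a case's retained alleles into a diagnosis status."""
    n_plp = sum(a.count for a in g.alleles if a.tier in PLP_TIERS)
    n_vus = sum(a.count for a in g.alleles if a.tier == "qualifying_VUS")
    if n_plp >= 2:
        status = "solved_PLP"
    elif n_plp == 1 and n_vus >= 1:
        status = "solved_with_VUS"
    elif n_plp == 1:
        status = "monoallelic"
    else:
        status = "unsolved"
    referral = status in ("monoallelic", "unsolved") and not g.external_solution
    return CaseResolution(sample_id=g.sample_id, phenotype=g.phenotype,
                          status=status, n_plp_alleles=n_plp,
                          n_qualifying_vus=n_vus, wgs_referral=referral,
                          alleles=g.alleles)


def _percent(numerator: int, denominator: int, convention: str) -> int:
    if denominator == 0:
        return 0
    x = 100 * numerator / denominator
    if convention == "truncate":
        return math.floor(x)
    if convention == "round":
        return math.floor(x + 0.5)  # round half up
    raise ValueError(f"unknown percentage convention {convention!r}")


@dataclass
class CohortSummary:
    counts: dict[str, dict[str, int]]  # phenotype -> status -> count
    solved_inclusive: int  # solved_PLP + solved_with_VUS
    solved_strict: int  # solved_PLP only
    total: int
    percent_solved: int
    percent_by_phenotype: dict[str, int]
    referrals: list[str]
    convention: str


def summarize_cohort(resolutions: list[CaseResolution],
                     convention: str = "round") -> CohortSummary:
    """Cohort-level yield: counts per status and phenotype, solve rates.

    Both solved tiers count toward the solve rate (a case with one P/LP
    allele plus a qualifying VUS received a working genetic diagnosis);
    the strict biallelic-P/LP count is reported alongside.  The integer
    percentage convention (round-half-up or truncate) is explicit because
    published yields mix both.
    """
    if not resolutions:
        raise ValueError("no case resolutions to summarize")
    phenotypes = sorted({r.phenotype for r in resolutions})
    counts = {ph: {s: 0 for s in STATUSES} for ph in phenotypes}
    for r in resolutions:
        counts[r.phenotype][r.status] += 1
    solved_inc = sum(counts[ph]["solved_PLP"] + counts[ph]["solved_with_VUS"]
                     for ph in phenotypes)
    solved_strict = sum(counts[ph]["solved_PLP"] for ph in phenotypes)
    total = len(resolutions)
    pct_by_ph = {}
    for ph in phenotypes:
        n_ph = sum(counts[ph].values())
        s_ph = counts[ph]["solved_PLP"] + counts[ph]["solved_with_VUS"]
        pct_by_ph[ph] = _percent(s_ph, n_ph, convention)
    return CohortSummary(
        counts=counts, solved_inclusive=solved_inc, solved_strict=solved_strict,
        total=total, percent_solved=_percent(solved_inc, total, convention),
        percent_by_phenotype=pct_by_ph,
        referrals=sorted(r.sample_id for r in resolutions if r.wgs_referral),
        convention=convention)


def wgs_referral_list(resolutions: list[CaseResolution],
                      external_solutions: list[str] = ()) -> list[str]:
    """Unresolved cases minus those explained outside the target gene."""
    ext = set(external_solutions)
    return sorted(r.sample_id for r in resolutions
                  if r.status in ("monoallelic", "unsolved")
                  and r.sample_id not in ext)


# -- wiring from pipeline tables ---------------------------------------

def cnv_allele_tier(call: CnvCall) -> str:
    """Frame-based operational tier for a CNV allele."""
    return "likely_pathogenic" if call.in_frame else "pathogenic"


def build_case_genotypes(manifest: pd.DataFrame, decisions: pd.DataFrame,
                         cnv_calls: list[CnvCall],
                         cnv_flags: pd.DataFrame | None = None) -> list[CaseGenotype]:
    """Assemble per-case genotypes from triage decisions and CNV calls.

    ``cnv_flags`` (sample_id, first_mip, last_mip, qpcr_confirmed,
    homozygous) carries the wet-lab knowledge the pipeline itself cannot
    infer: orthogonal confirmation of sub-run-length events and zygosity.
    """
    flags = cnv_flags if cnv_flags is not None else pd.DataFrame(
        columns=["sample_id", "first_mip", "last_mip", "qpcr_confirmed",
                 "homozygous"])
    genotypes = []
    kept = decisions[decisions["kept"] & decisions["tier"].isin(
        PLP_TIERS + ("qualifying_VUS",))]
    for row in manifest.itertuples(index=False):
        sid = row.sample_id
        alleles = [Allele(description=r.hgvs_c, tier=r.tier,
                          homozygous=bool(r.homozygous))
                   for r in kept[kept["sample_id"] == sid].itertuples(index=False)]
        sample_flags = flags[flags["sample_id"] == sid]
        for call in (c for c in cnv_calls if c.sample_id == sid):
            matching = sample_flags[
                (sample_flags["first_mip"] <= call.last_mip_index)
                & (sample_flags["last_mip"] >= call.first_mip_index)]
            confirmed = bool(matching["qpcr_confirmed"].any())
            homozygous = bool(matching["homozygous"].any()) and call.likely_homozygous
            if call.status == "qpcr_followup" and not confirmed:
                continue
            desc = f"{call.type}(exons {call.exon_span})"
            alleles.append(Allele(description=desc, tier=cnv_allele_tier(call),
                                  is_cnv=True, homozygous=homozygous))
        genotypes.append(CaseGenotype(
            sample_id=sid, phenotype=row.phenotype, alleles=alleles,
            prescreened_allele=getattr(row, "prescreened_allele", ""),
            external_solution=bool(getattr(row, "external_solution", False))))
    return genotypes
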