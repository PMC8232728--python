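"""Case resolution and cohort summary logic."""

import pytest

from mipscreen.resolve import (Allele, CaseGenotype, CaseResolution,
                               resolve_case, summarize_cohort,
                               wgs_referral_list)


def _case(tiers, phenotype="USH2", sid="S1", hom=None, external=False):
    hom = hom or []
    alleles = [Allele(description=f"v{i}", tier=t, homozygous=i in hom)
               for i, t in enumerate(tiers)]
    return CaseGenotype(sample_id=sid, phenotype=phenotype, alleles=alleles,
                        external_solution=external)


@pytest.mark.parametrize("tiers,hom,expected", [
    (["pathogenic", "pathogenic"], [], "solved_PLP"),
    (["pathogenic", "likely_pathogenic"], [], "solved_PLP"),
    (["pathogenic"], [0], "solved_PLP"),            # homozygous counts twice
    (["pathogenic", "qualifying_VUS"], [], "solved_with_VUS"),
    (["pathogenic"], [], "monoallelic"),
    (["qualifying_VUS"], [], "unsolved"),           # VUS alone solves nothing
    (["qualifying_VUS", "qualifying_VUS"], [], "unsolved"),
    ([], [], "unsolved"),
])
def test_resolve_case_statuses(tiers, hom, expected):
    assert resolve_case(_case(tiers, hom=hom)).status == expected


def test_homozygous_needs_explicit_flag():
    # the same allele without the flag counts once
    assert resolve_case(_case(["pathogenic"])).status == "monoallelic"
    assert resolve_case(_case(["pathogenic"], hom=[0])).status == "solved_PLP"


def test_duplicate_alleles_deduplicated():
    g = CaseGenotype(sample_id="S", phenotype="USH2", alleles=[
        Allele("c.2299del", "pathogenic"), Allele("c.2299del", "pathogenic")])
    assert resolve_case(g).status == "monoallelic"


def test_monotone_in_evidence():
    """Adding an allele never demotes the case status."""
    order = {"unsolved": 0, "monoallelic": 1, "solved_with_VUS": 2,
             "solved_PLP": 3}
    base_tiers = [[], ["pathogenic"], ["pathogenic", "qualifying_VUS"]]
    for tiers in base_tiers:
        before = resolve_case(_case(list(tiers))).status
        for extra in ("pathogenic", "likely_pathogenic", "qualifying_VUS"):
            after = resolve_case(_case(list(tiers) + [extra])).status
            assert order[after] >= order[before]


def _resolutions(spec):
    """spec: list of (phenotype, status, external) triples."""
    out = []
    for i, (ph, status, ext) in enumerate(spec):
        out.append(CaseResolution(
            sample_id=f"S{i:02d}", phenotype=ph, status=status,
            n_plp_alleles=2 if status == "solved_PLP" else 1,
            n_qualifying_vus=1 if status == "solved_with_VUS" else 0,
            wgs_referral=status in ("monoallelic", "unsolved") and not ext))
    return out


def _mirror_resolutions():
    spec = ([("USH2", "solved_PLP", False)] * 24
            + [("USH2", "solved_with_VUS", False)] * 2
            + [("USH2", "monoallelic", False)] * 2
            + [("USH2", "unsolved", True)]
            + [("arRP", "solved_PLP", False)] * 5
            + [("arRP", "solved_with_VUS", False)]
            + [("arRP", "monoallelic", False)] * 5)
    return _resolutions(spec)


def test_summary_counts_partition_cohort():
    s = summarize_cohort(_mirror_resolutions())
    assert s.total == 40
    for ph in ("USH2", "arRP"):
        assert sum(s.counts[ph].values()) == {"USH2": 29, "arRP": 11}[ph]
    assert s.solved_inclusive == 32
    assert s.solved_strict == 29


def test_summary_percentages_round_half_up():
    s = summarize_cohort(_mirror_resolutions(), convention="round")
    assert s.percent_solved == 80          # 32/40
    assert s.percent_by_phenotype["USH2"] == 90   # 26/29 = 89.7
    assert s.percent_by_phenotype["arRP"] == 55   # 6/11 = 54.5 rounds up


def test_summary_percentages_truncate():
    s = summarize_cohort(_mirror_resolutions(), convention="truncate")
    assert s.percent_by_phenotype["arRP"] == 54
    assert s.percent_by_phenotype["USH2"] == 89
    assert s.percent_solved == 80


def test_zero_solved_percent():
    res = _resolutions([("USH2", "unsolved", False)] * 3)
    s = summarize_cohort(res)
    assert s.percent_solved == 0


def test_wgs_referrals_exclude_externally_solved():
    res = _mirror_resolutions()
    # 8 unresolved cases, one of them explained outside the gene
    assert len(wgs_referral_list(res)) == 8
    ext = [r.sample_id for r in res if r.status == "unsolved"]
    assert len(wgs_referral_list(res, external_solutions=ext)) == 7
    assert len(summarize_cohort(res).referrals) == 7  # external flag applied


def test_all_solved_no_referrals():
    res = _resolutions([("USH2", "solved_PLP", False)] * 4)
    assert wgs_referral_list(res) == []


def test_empty_cohort_rejected():
    with pytest.raises(ValueError):
        summarize_cohort([])
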