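"""Variant triage cascade: filters, missense criteria, splice gate, tiers."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mipscreen.triage import (VariantRecord, assign_tier, filter_af,
                              filter_edge_artifact, filter_read_fraction,
                              missense_criteria, splice_assay_gate)

NAN = float("nan")


def make_variant(**kw):
    base = dict(sample_id="S1", hgvs_c="c.1000A>G", consequence="missense",
                hgvs_p="p.(Lys334Arg)", read_fraction=0.5)
    base.update(kw)
    return VariantRecord(**base)


def test_consequence_consistency_enforced():
    with pytest.raises(ValueError):
        make_variant(hgvs_c="c.9258+1G>A", consequence="intronic")
    with pytest.raises(ValueError):
        make_variant(hgvs_c="c.1000A>G", consequence="canonical_splice")


@pytest.mark.parametrize("maf,keep", [
    (0.05, False),   # common variant dropped
    (0.01, True),    # ceiling is inclusive
    (NAN, True),     # novel variant kept
    (0.0005, True),
])
def test_filter_af(maf, keep):
    assert filter_af(make_variant(maf=maf)) is keep


@pytest.mark.parametrize("rf,db,keep", [
    (0.10, "ClinVar:likely_pathogenic", True),   # database rescues low rf
    (0.10, "none", False),
    (0.50, "none", True),
    (0.15, "none", True),                        # floor is inclusive
    (0.08, "LOVD:benign", True),                 # any database record counts
])
def test_filter_read_fraction(rf, db, keep):
    assert filter_read_fraction(make_variant(read_fraction=rf, db_status=db)) is keep


def test_filter_edge_artifact(panel):
    # find a probe whose terminal nucleotide is inside an overlapping probe
    probe = other_ids = None
    for p in panel.probes:
        others = [q.mip_id for q in panel.probes_overlapping(p.end)
                  if q.mip_id != p.mip_id]
        if others:
            probe, other_ids = p, others
            break
    assert probe is not None, "tiling should double-cover some probe ends"
    at_edge = make_variant(genomic_pos=probe.end)
    # unsupported in the overlapping probe -> artifact, dropped
    assert filter_edge_artifact(at_edge, panel,
                                {probe.mip_id: True, other_ids[0]: False}) is False
    # supported in the overlapping probe -> kept
    assert filter_edge_artifact(at_edge, panel,
                                {probe.mip_id: True, other_ids[0]: True}) is True
    # interior position is never an edge artifact
    interior = make_variant(genomic_pos=probe.start + 50)
    assert filter_edge_artifact(interior, panel, {}) is True


@pytest.mark.parametrize("gr,cadd,phylop,sift,mt,count", [
    (184, 25.5, 5.06, "Deleterious", "Disease causing", 5),
    (144, 26.1, 4.17, "Deleterious", "Disease causing", 5),
    (10, 2.0, 0.0, "Tolerated", "Polymorphism", 0),
    (80, 15.0, 2.7, "Tolerated", "Polymorphism", 3),  # thresholds inclusive
    (79, 14.9, 2.69, "Deleterious", "Disease causing", 2),
    (NAN, 25.0, 5.0, "Deleterious", "Disease causing", 4),  # missing = unmet
])
def test_missense_criteria_counting(gr, cadd, phylop, sift, mt, count):
    v = make_variant(grantham=gr, cadd=cadd, phylop=phylop, sift=sift, mtaster=mt)
    got, passed = missense_criteria(v)
    assert got == count
    assert passed is (count >= 4)


@settings(max_examples=200, derandomize=True)
@given(gr=st.integers(0, 215), cadd=st.floats(0, 99), phylop=st.floats(-5, 10),
       sift=st.sampled_from(["Deleterious", "Tolerated", "n/a"]),
       mt=st.sampled_from(["Disease causing", "Polymorphism", "n/a"]))
def test_missense_criteria_monotone(gr, cadd, phylop, sift, mt):
    """Improving any single score never decreases the criteria count."""
    v = make_variant(grantham=gr, cadd=cadd, phylop=phylop, sift=sift, mtaster=mt)
    count, _ = missense_criteria(v)
    better = make_variant(grantham=min(gr + 50, 215), cadd=min(cadd + 20, 99),
                          phylop=phylop + 5, sift="Deleterious",
                          mtaster="Disease causing")
    count_b, _ = missense_criteria(better)
    assert count_b >= count


@pytest.mark.parametrize("deltas,consequence,cis,expected", [
    ((0.65, 0.4, 0.0, 0.0), "synonymous", False, True),
    ((0.9, 0.9, 0.0, 0.0), "canonical_splice", False, False),
    ((0.19, 0.19, 0.19, 0.19), "synonymous", False, False),  # all below 0.2
    ((0.2, 0.2, 0.0, 0.0), "intronic", False, True),  # threshold inclusive
    ((0.9, 0.9, 0.9, 0.9), "stop_gain", False, False),
    ((0.65, 0.4, 0.0, 0.0), "synonymous", True, False),  # in cis with stop
    ((0.27, 0.0, 0.0, 0.0), "intronic", False, False),  # single hit
])
def test_splice_assay_gate(deltas, consequence, cis, expected):
    hgvs = {"canonical_splice": "c.9258+1G>A", "intronic": "c.14583-20C>G"}.get(
        consequence, "c.1000A>G")
    v = make_variant(hgvs_c=hgvs, consequence=consequence, spliceai=deltas,
                     in_cis_with_stopgain=cis)
    assert splice_assay_gate(v) is expected


def test_tier_stop_gain_pathogenic():
    v = make_variant(hgvs_c="c.11683G>T", hgvs_p="p.(Gly3895*)",
                     consequence="stop_gain", cadd=55.0)
    d = assign_tier(v)
    assert d.kept and d.tier == "pathogenic"
    assert not d.splice_assay_candidate


def test_tier_expert_panel_benign_excluded():
    v = make_variant(hgvs_c="c.12575G>A", consequence="missense",
                     db_status="ClinVar:benign", maf=0.004)
    d = assign_tier(v)
    assert not d.kept
    assert d.drop_reason == "benign_db"
    assert d.tier == "excluded"


def test_tier_low_rf_database_variant_kept():
    v = make_variant(hgvs_c="c.7067A>G", consequence="missense",
                     read_fraction=0.10, db_status="ClinVar:likely_pathogenic",
                     grantham=46, cadd=22.0, phylop=2.9)
    d = assign_tier(v)
    assert d.kept and d.tier == "likely_pathogenic"


def test_tier_qualifying_vus():
    v = make_variant(grantham=94, cadd=24.1, phylop=3.9, sift="Deleterious",
                     mtaster="Disease causing")
    d = assign_tier(v)
    assert d.tier == "qualifying_VUS"
    assert d.missense_criteria_met == 5


def test_tier_splice_candidate_vus_until_confirmed():
    v = make_variant(hgvs_c="c.8709C>T", consequence="synonymous",
                     spliceai=(0.65, 0.4, 0.0, 0.0))
    d = assign_tier(v)
    assert d.tier == "VUS" and d.splice_assay_candidate
    confirmed = make_variant(hgvs_c="c.8709C>T", consequence="synonymous",
                             spliceai=(0.65, 0.4, 0.0, 0.0),
                             functionally_confirmed=True)
    assert assign_tier(confirmed).tier == "pathogenic"


def test_filter_order_invariance(panel):
    """The kept/dropped partition is the conjunction of three pure
    predicates, hence identical under any filter ordering."""
    rng = np.random.default_rng(0)
    variants = []
    for _ in range(80):
        probe = panel[int(rng.integers(len(panel)))]
        edge = bool(rng.integers(2))
        pos = probe.end if edge else probe.start + 40
        variants.append(make_variant(
            maf=float(rng.choice([NAN, 0.001, 0.05])),
            read_fraction=float(rng.choice([0.08, 0.5])),
            genomic_pos=pos,
            db_status=str(rng.choice(["none", "LOVD:pathogenic"])),
            probe_support={p.mip_id: bool(rng.integers(2))
                           for p in panel.probes_overlapping(pos)}))
    filters = [filter_af, filter_read_fraction,
               lambda v: filter_edge_artifact(v, panel)]
    results = []
    for order in itertools.permutations(range(3)):
        results.append([all(filters[k](v) for k in order) for v in variants])
    assert all(r == results[0] for r in results)
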