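"""Synthetic cohort generator: statistical structure and planted truth."""

import math

import numpy as np
import pandas as pd
import pytest

from mipscreen.cnv import call_cnvs, normalize
from mipscreen.simulate import (CATALOG, CnvEvent, CohortSpec, CoverageSimSpec,
                                inject_annotation_noise, mirror_cohort,
                                simulate_cohort, simulate_coverage)
from mipscreen.triage import triage_table


def test_coverage_shape_and_determinism(panel):
    spec = CoverageSimSpec()
    a = simulate_coverage(panel, 5, spec, seed=3)
    b = simulate_coverage(panel, 5, spec, seed=3)
    assert a.shape == (5, len(panel))
    pd.testing.assert_frame_equal(a, b)
    c = simulate_coverage(panel, 5, spec, seed=4)
    assert not a.equals(c)


def test_noise_free_limit(panel):
    # infinite NB size parameter leaves only counting (Poisson) noise,
    # which is negligible relative to the mean at ~1488x
    spec = CoverageSimSpec(dispersion=math.inf, efficiency_sigma=0.0)
    cov = simulate_coverage(panel, 10, spec, seed=0)
    cv = cov.to_numpy().std() / cov.to_numpy().mean()
    assert cov.to_numpy().mean() == pytest.approx(1488, rel=0.01)
    assert cv < 0.05


def test_het_deletion_halves_coverage(panel):
    ev = CnvEvent(sample_id="S001", first_mip_index=40, n_mips=8, copy_state=1)
    spec = CoverageSimSpec(cnv_events=[ev], efficiency_sigma=0.0)
    cov = simulate_coverage(panel, 40, spec, seed=1)
    inside = cov.iloc[0, 40:48].mean()
    # binomial-thinning expectation: half depth, within 3 standard errors
    se = math.sqrt(1488 / 2 * (1 + 744 / spec.dispersion) / 8)
    assert abs(inside - 744) < 3 * se
    outside = cov.iloc[1:, 40:48].to_numpy().mean()
    assert outside == pytest.approx(1488, rel=0.02)


def test_homozygous_loss_is_residual_not_zero(panel):
    ev = CnvEvent(sample_id="S001", first_mip_index=10, n_mips=7, copy_state=0)
    spec = CoverageSimSpec(cnv_events=[ev], efficiency_sigma=0.0)
    cov = simulate_coverage(panel, 5, spec, seed=2)
    inside = cov.iloc[0, 10:17].to_numpy()
    assert inside.mean() < 0.1 * 1488
    assert inside.sum() > 0


def test_dropout_mips_are_zero(panel):
    spec = CoverageSimSpec(dropout_mips=[3, 17])
    cov = simulate_coverage(panel, 6, spec, seed=5)
    assert (cov.iloc[:, 3] == 0).all()
    assert (cov.iloc[:, 17] == 0).all()


def test_copy_state_two_rejected():
    with pytest.raises(ValueError):
        CnvEvent(sample_id="S", first_mip_index=0, n_mips=3, copy_state=2)


def test_normalized_median_near_one(panel):
    cov = simulate_coverage(panel, 40, CoverageSimSpec(), seed=11)
    norm = normalize(cov)
    med = np.nanmedian(norm.values.to_numpy())
    assert abs(med - 1.0) < 0.05


def test_cohort_spec_validation():
    with pytest.raises(ValueError):
        CohortSpec(genotype_mix={"biallelic_PLP": 0.5, "none": 0.4})
    with pytest.raises(ValueError):
        CohortSpec(n_ush2=-1)


def test_all_biallelic_cohort_fully_solvable(panel, model):
    from mipscreen.resolve import build_case_genotypes, resolve_case
    spec = CohortSpec(n_ush2=5, n_arrp=0,
                      genotype_mix={"biallelic_PLP": 1.0}, seed=9)
    truth, table, cov = simulate_cohort(spec, panel, model)
    decisions = triage_table(table, panel)
    genotypes = build_case_genotypes(truth.manifest, decisions, [], truth.cnv_flags)
    statuses = [resolve_case(g).status for g in genotypes]
    assert statuses == ["solved_PLP"] * 5


def test_same_seed_same_tables(panel, model):
    spec = CohortSpec(n_ush2=4, n_arrp=2, seed=13)
    t1, v1, c1 = simulate_cohort(spec, panel, model)
    t2, v2, c2 = simulate_cohort(spec, panel, model)
    pd.testing.assert_frame_equal(v1, v2)
    pd.testing.assert_frame_equal(c1, c2)
    assert [a.hgvs_c for a in t1.variants] == [a.hgvs_c for a in t2.variants]


def test_inject_noise_zero_fraction_is_identity(panel, model):
    spec = CohortSpec(n_ush2=3, n_arrp=0, seed=1)
    _, table, _ = simulate_cohort(spec, panel, model)
    out = inject_annotation_noise(table, 0.0, 1, panel, model)
    pd.testing.assert_frame_equal(out, table)


def test_decoys_all_removed_with_matching_reason(panel, model):
    """Planted-truth recovery: every decoy is dropped by the cascade and
    for the planted reason; every planted allele is kept."""
    truth, table, _ = mirror_cohort(panel, model, seed=21,
                                          benign_fraction=2.0)
    decisions = triage_table(table, panel)
    key = decisions.set_index(["sample_id", "hgvs_c"])
    for pv in truth.variants:
        row = key.loc[(pv.sample_id, pv.hgvs_c)]
        if isinstance(row, pd.DataFrame):
            row = row.iloc[0]
        assert bool(row["kept"]) is pv.expected_kept, pv
        if not pv.expected_kept:
            assert row["drop_reason"] == pv.expected_drop_reason, pv


def test_mirror_cohort_composition(panel, model):
    truth, table, cov = mirror_cohort(panel, model, seed=3)
    m = truth.manifest
    assert len(m) == 40
    assert (m.phenotype == "USH2").sum() == 29
    assert (m.phenotype == "arRP").sum() == 11
    assert cov.shape[0] == 40
    # nine CNV alleles over four distinct events (one homozygous carrier)
    assert sum(2 if e.homozygous else 1 for e in truth.cnv_events) == 9
    assert len({e.hgvs_c for e in truth.cnv_events}) == 4
    # CNV alleles never appear in the SNV table
    cnv_names = {e.hgvs_c for e in truth.cnv_events}
    assert not (table["hgvs_c"].isin(cnv_names)).any()


def test_mirror_catalog_annotations_satisfy_their_rules():
    row = CATALOG["c.9388T>G"]
    assert row["grantham"] >= 80 and row["cadd"] >= 15 and row["phylop"] >= 2.7
    assert CATALOG["c.8709C>T"]["sai_ag"] >= 0.2
    assert CATALOG["c.12575G>A"]["db_status"] == "ClinVar:benign"
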