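"""Normalization, run-length CNV calling (with brute-force oracle) and
low-coverage reporting."""

import numpy as np
import pandas as pd
import pytest

from mipscreen.cnv import (CnvCall, NormalizedCoverage, annotate_cnv, call_cnvs,
                           low_coverage_report, normalize)
from mipscreen.simulate import CnvEvent, CoverageSimSpec, simulate_coverage


def _norm_from_matrix(mat, excluded=()):
    df = pd.DataFrame(np.asarray(mat, dtype=float))
    df.columns = [f"M{i}" for i in range(df.shape[1])]
    df.index = [f"S{i}" for i in range(df.shape[0])]
    values = df.copy()
    excluded_ids = [f"M{i}" for i in excluded]
    values[excluded_ids] = np.nan
    return NormalizedCoverage(values=values, excluded_mips=excluded_ids,
                              sample_scale=pd.Series(1.0, index=df.index))


# -- normalization -----------------------------------------------------

def test_constant_matrix_normalizes_to_one():
    raw = pd.DataFrame(500, index=list("abc"), columns=[f"M{i}" for i in range(10)])
    norm = normalize(raw)
    assert np.allclose(norm.values.to_numpy(), 1.0)


def test_half_depth_sample_rescaled_to_one():
    raw = pd.DataFrame(1000, index=list("abcd"), columns=[f"M{i}" for i in range(12)])
    raw.iloc[2] = 500
    norm = normalize(raw)
    assert np.allclose(norm.values.to_numpy(), 1.0)


def test_scale_invariance_per_sample():
    rng = np.random.default_rng(0)
    raw = pd.DataFrame(rng.integers(100, 3000, size=(6, 30)).astype(float),
                       index=[f"S{i}" for i in range(6)],
                       columns=[f"M{i}" for i in range(30)])
    a = normalize(raw)
    scaled = raw.copy()
    scaled.iloc[2] *= 7.3
    b = normalize(scaled)
    pd.testing.assert_frame_equal(a.values, b.values)


def test_cohort_median_is_one_per_mip():
    rng = np.random.default_rng(1)
    raw = pd.DataFrame(rng.poisson(1000, size=(9, 25)).astype(float))
    raw.columns = [f"M{i}" for i in range(25)]
    norm = normalize(raw)
    med = norm.values.median(axis=0)
    assert np.allclose(med[norm.included_mips], 1.0)


def test_low_median_mips_excluded():
    raw = pd.DataFrame(1000.0, index=list("abc"), columns=[f"M{i}" for i in range(5)])
    raw["M2"] = 5.0
    norm = normalize(raw, median_floor=20)
    assert norm.excluded_mips == ["M2"]
    assert norm.values["M2"].isna().all()


def test_all_zero_sample_rejected():
    raw = pd.DataFrame(1000, index=list("abc"), columns=[f"M{i}" for i in range(5)])
    raw.iloc[1] = 0
    with pytest.raises(ValueError, match="b"):
        normalize(raw)


def test_fewer_than_three_samples_rejected():
    raw = pd.DataFrame(1000, index=list("ab"), columns=[f"M{i}" for i in range(5)])
    with pytest.raises(ValueError):
        normalize(raw)


def test_planted_deletion_ratio_near_half(panel):
    ev = CnvEvent(sample_id="S001", first_mip_index=60, n_mips=8, copy_state=1)
    cov = simulate_coverage(panel, 40, CoverageSimSpec(cnv_events=[ev]), seed=8)
    norm = normalize(cov)
    run = norm.values.iloc[0, 60:68]
    assert 0.4 < run.mean() < 0.6


# -- run-length calling: rule traces -----------------------------------

def test_flat_matrix_no_calls():
    norm = _norm_from_matrix(np.ones((3, 20)))
    assert call_cnvs(norm) == []


def test_eight_mip_deletion_called():
    mat = np.ones((2, 60))
    mat[0, 40:48] = 0.5
    calls = call_cnvs(_norm_from_matrix(mat))
    assert len(calls) == 1
    c = calls[0]
    assert (c.sample_id, c.type, c.status) == ("S0", "deletion", "called")
    assert (c.first_mip_index, c.last_mip_index, c.n_mips) == (40, 47, 8)


def test_six_mip_deletion_is_qpcr_tier():
    mat = np.ones((2, 30))
    mat[1, 10:16] = 0.5
    calls = call_cnvs(_norm_from_matrix(mat))
    assert [c.status for c in calls] == ["qpcr_followup"]
    assert calls[0].n_mips == 6


def test_singleton_excursion_ignored():
    mat = np.ones((1, 20))
    mat[0, 5] = 0.1
    assert call_cnvs(_norm_from_matrix(mat), merge_gap=0) == []


def test_duplication_called_at_threshold():
    # ties at exactly 1.3 / 0.7 are inclusive
    mat = np.ones((1, 20))
    mat[0, 3:10] = 1.3
    calls = call_cnvs(_norm_from_matrix(mat))
    assert [c.type for c in calls] == ["duplication"]
    assert calls[0].status == "called"
    mat[0, 3:10] = 0.7
    calls = call_cnvs(_norm_from_matrix(mat))
    assert [c.type for c in calls] == ["deletion"]


def test_excluded_mip_bridges_run():
    mat = np.ones((1, 20))
    mat[0, 4:12] = 0.5
    norm = _norm_from_matrix(mat, excluded=[7])
    calls = call_cnvs(norm)
    assert len(calls) == 1
    c = calls[0]
    assert (c.first_mip_index, c.last_mip_index) == (4, 11)
    assert c.n_mips == 7  # the excluded probe does not count
    assert c.status == "called"


def test_merge_gap_spans_single_discordant_probe():
    mat = np.ones((1, 40))
    mat[0, 10:30] = 0.5
    mat[0, 20] = 1.0  # one probe fluctuates back to diploid
    calls = call_cnvs(_norm_from_matrix(mat), merge_gap=1)
    assert len(calls) == 1
    assert (calls[0].first_mip_index, calls[0].last_mip_index) == (10, 29)
    assert calls[0].n_mips == 19
    strict = call_cnvs(_norm_from_matrix(mat), merge_gap=0)
    assert len(strict) == 2


def test_likely_homozygous_band():
    mat = np.ones((1, 20))
    mat[0, 2:12] = 0.02
    calls = call_cnvs(_norm_from_matrix(mat))
    assert calls[0].likely_homozygous
    mat[0, 2:12] = 0.5
    calls = call_cnvs(_norm_from_matrix(mat))
    assert not calls[0].likely_homozygous


# -- oracle equivalence ------------------------------------------------

def brute_force_calls(values, del_thresh=0.7, dup_thresh=1.3, min_run=7,
                      min_followup=2, merge_gap=1):
    """Independent O(n^2) reference: enumerate every interval, keep the
    maximal ones whose cells all qualify for one state, then merge runs
    separated by <= merge_gap discordant cells."""
    out = []
    n_samples, n_mips = values.shape
    for s in range(n_samples):
        row = values[s]
        states = {-1: row <= del_thresh, 1: row >= dup_thresh}
        for state, ok in states.items():
            other = states[-state]
            runs = []
            for i in range(n_mips):
                for j in range(i, n_mips):
                    if all(ok[i:j + 1]) and (i == 0 or not ok[i - 1]) \
                            and (j == n_mips - 1 or not ok[j + 1]):
                        runs.append([i, j])
            runs.sort()
            merged = []
            for r in runs:
                gap = range(merged[-1][1] + 1, r[0]) if merged else range(0)
                if merged and r[0] - merged[-1][1] - 1 <= merge_gap \
                        and not any(other[k] for k in gap):
                    merged[-1][1] = r[1]
                else:
                    merged.append(r)
            for i, j in merged:
                n_q = int(ok[i:j + 1].sum())
                if n_q >= min_followup:
                    out.append((s, i, j, state,
                                "called" if n_q >= min_run else "qpcr_followup"))
    return sorted(out)


@pytest.mark.parametrize("merge_gap", [0, 1])
def test_oracle_equivalence_random_matrices(merge_gap):
    rng = np.random.default_rng(2024)
    for _ in range(200):
        n_s = int(rng.integers(1, 5))
        n_m = int(rng.integers(8, 51))
        values = rng.choice([0.4, 0.65, 0.7, 1.0, 1.3, 1.6],
                            size=(n_s, n_m),
                            p=[0.1, 0.08, 0.07, 0.55, 0.1, 0.1])
        norm = _norm_from_matrix(values)
        got = sorted((int(c.sample_id[1:]), c.first_mip_index, c.last_mip_index,
                      -1 if c.type == "deletion" else 1, c.status)
                     for c in call_cnvs(norm, merge_gap=merge_gap))
        assert got == brute_force_calls(values, merge_gap=merge_gap)


def test_threshold_monotonicity():
    """Raising del_thresh never removes a deletion; lowering min_run never
    removes a called event."""
    rng = np.random.default_rng(5)
    values = rng.choice([0.4, 0.72, 1.0], size=(4, 40), p=[0.25, 0.15, 0.6])
    norm = _norm_from_matrix(values)
    base = {(c.sample_id, c.first_mip_index, c.last_mip_index)
            for c in call_cnvs(norm, del_thresh=0.7) if c.type == "deletion"}
    wider = call_cnvs(norm, del_thresh=0.75)
    wider_members = []
    for c in wider:
        if c.type == "deletion":
            wider_members.append((c.sample_id, c.first_mip_index, c.last_mip_index))
    for sid, i, j in base:
        assert any(s == sid and wi <= i and wj >= j for s, wi, wj in wider_members)
    called7 = [c for c in call_cnvs(norm, min_run=7) if c.status == "called"]
    called5 = {(c.sample_id, c.first_mip_index) for c in call_cnvs(norm, min_run=5)
               if c.status == "called"}
    for c in called7:
        assert (c.sample_id, c.first_mip_index) in called5


# -- annotation --------------------------------------------------------

def _call(first, last, type_="deletion"):
    return CnvCall(sample_id="S", first_mip_index=first, last_mip_index=last,
                   type=type_, n_mips=last - first + 1, mean_ratio=0.5,
                   status="called")


def _probe_range_for_exons(panel, model, first_exon, last_exon):
    g1 = model.exon(first_exon).genomic_start - 20
    g2 = model.exon(last_exon).genomic_end + 20
    probes = panel.probes_within(g1, g2)
    return probes[0].panel_index, probes[-1].panel_index


def test_annotate_single_exon_inframe(panel, model):
    i, j = _probe_range_for_exons(panel, model, 43, 43)
    call = annotate_cnv(_call(i, j), panel, model)
    assert call.exon_span == "43"
    assert call.deleted_nt == 123
    assert call.in_frame is True
    assert call.aa_count == 41


def test_annotate_multi_exon_span(panel, model):
    i, j = _probe_range_for_exons(panel, model, 38, 56)
    call = annotate_cnv(_call(i, j), panel, model)
    assert call.exon_span == "38-56"
    assert call.deleted_nt == 3927
    assert call.in_frame is True


def test_annotate_out_of_frame_exon(panel, model):
    # fixture exon 37 is 153 nt (in frame); exon 39 is 241 nt (not)
    i, j = _probe_range_for_exons(panel, model, 39, 39)
    call = annotate_cnv(_call(i, j), panel, model)
    assert call.deleted_nt == 241
    assert call.in_frame is False
    assert call.aa_count is None


# -- low-coverage report -----------------------------------------------

def test_low_coverage_empty_when_all_covered():
    raw = pd.DataFrame(50, index=list("ab"), columns=[f"M{i}" for i in range(6)])
    assert low_coverage_report(raw) == []


def test_low_coverage_tiers():
    raw = pd.DataFrame(50, index=list("ab"), columns=[f"M{i}" for i in range(8)])
    raw.iloc[0, 2] = 7   # below 10 -> manual check only
    raw.iloc[1, 5] = 0   # below 5 -> both tiers
    regions = low_coverage_report(raw)
    assert len(regions) == 2
    manual = next(r for r in regions if r.sample_id == "a")
    assert manual.tier == "manual_check" and not manual.sanger
    sanger = next(r for r in regions if r.sample_id == "b")
    assert sanger.tier == "sanger" and sanger.manual_check and sanger.sanger


def test_low_coverage_runs_are_maximal():
    raw = pd.DataFrame(50, index=["a"], columns=[f"M{i}" for i in range(10)])
    raw.iloc[0, 3:7] = [4, 8, 9, 2]
    regions = low_coverage_report(raw)
    assert len(regions) == 1
    r = regions[0]
    assert (r.first_mip_index, r.last_mip_index, r.min_reads) == (3, 6, 2)
    assert r.sanger
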