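"""Per-wavenumber statistics, density overlap and feature selection."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from irscreen import (
    pdf_overlap,
    pointwise_ttest,
    select_features,
    subgroup_trace,
)
from irscreen.grid import WavenumberGrid
from irscreen.spectra import SpectralDataset


def _dataset(matrix, labels=None, grid=None, component="PBMC"):
    matrix = np.atleast_2d(np.asarray(matrix, dtype=float))
    n, p = matrix.shape
    if grid is None:
        grid = WavenumberGrid(700.0 + np.arange(p, dtype=float))
    labels = labels if labels is not None else ["control"] * n
    return SpectralDataset(
        matrix=matrix,
        grid=grid,
        subject_ids=[f"S{i:03d}" for i in range(n)],
        labels=np.asarray(labels, dtype=object),
        component=component,
    )


# -- t-test -----------------------------------------------------------------


def test_identical_groups_give_t0_p1(rng):
    rows = rng.normal(size=(4, 6))
    trace = pointwise_ttest(_dataset(rows), _dataset(rows))
    np.testing.assert_allclose(trace.t_stats, 0.0, atol=1e-12)
    np.testing.assert_allclose(trace.p_values, 1.0)


def test_welch_p_matches_t_distribution_oracle():
    """A=[1,2,3], B=[2,3,4]: t = -1.2247, Welch df = 4, two-sided p computed
    directly from the t CDF."""
    trace = pointwise_ttest(
        _dataset([[1.0, 1.0], [2.0, 2.0], [3.0, 3.0]]),
        _dataset([[2.0, 2.0], [3.0, 3.0], [4.0, 4.0]]),
    )
    assert trace.t_stats[0] == pytest.approx(-1.2247448714, abs=1e-9)
    assert trace.p_values[0] == pytest.approx(0.2878641347, abs=1e-9)


def test_pooled_flag_gives_classical_student_test(rng):
    from scipy import stats

    a, b = rng.normal(size=(5, 4)), rng.normal(1.0, 2.0, size=(7, 4))
    trace = pointwise_ttest(_dataset(a), _dataset(b), pooled=True)
    t_ref, p_ref = stats.ttest_ind(a, b, axis=0, equal_var=True)
    np.testing.assert_allclose(trace.t_stats, t_ref)
    np.testing.assert_allclose(trace.p_values, p_ref)


@settings(deadline=None, max_examples=25, derandomize=True)
@given(
    shift=st.floats(-50, 50, allow_nan=False),
    seed=st.integers(0, 10_000),
)
def test_ttest_invariant_to_shift_and_group_swap(shift, seed):
    rng = np.random.default_rng(seed)
    a, b = rng.normal(size=(5, 3)), rng.normal(0.5, 1.0, size=(6, 3))
    base = pointwise_ttest(_dataset(a), _dataset(b))
    shifted = pointwise_ttest(_dataset(a + shift), _dataset(b + shift))
    swapped = pointwise_ttest(_dataset(b), _dataset(a))
    np.testing.assert_allclose(shifted.p_values, base.p_values, rtol=1e-7)
    np.testing.assert_allclose(swapped.p_values, base.p_values, rtol=1e-10)
    np.testing.assert_allclose(swapped.t_stats, -base.t_stats, rtol=1e-10)


def test_ttest_rejects_tiny_groups_and_grid_mismatch(rng):
    with pytest.raises(ValueError, match="at least 2"):
        pointwise_ttest(_dataset(rng.normal(size=(1, 3))), _dataset(rng.normal(size=(3, 3))))
    other_grid = WavenumberGrid(900.0 + np.arange(3.0))
    with pytest.raises(ValueError, match="grid"):
        pointwise_ttest(
            _dataset(rng.normal(size=(3, 3))),
            _dataset(rng.normal(size=(3, 3)), grid=other_grid),
        )


def test_null_significance_fraction_is_calibrated():
    """Under independent null features the fraction with p < 0.005 matches the
    nominal level (20 seeds, 30 vs 30 subjects, 2282 wavenumbers)."""
    fractions = []
    for seed in range(20):
        rng = np.random.default_rng(seed)
        a = _dataset(rng.normal(size=(30, 2282)))
        b = _dataset(rng.normal(size=(30, 2282)))
        fractions.append((pointwise_ttest(a, b).p_values < 0.005).mean())
    assert np.mean(fractions) == pytest.approx(0.005, abs=0.004)


# -- OVL --------------------------------------------------------------------


def test_overlap_identical_and_disjoint(rng):
    x = rng.normal(size=200)
    assert pdf_overlap(x, x) == pytest.approx(1.0, abs=0.02)
    assert pdf_overlap(rng.normal(0, 1, 200), rng.normal(1000, 1, 200)) < 0.01


def test_overlap_matches_normal_closed_form(rng):
    """For N(0,1) vs N(2,1) the overlapping coefficient is 2*Phi(-1)."""
    a = rng.normal(0.0, 1.0, size=4000)
    b = rng.normal(2.0, 1.0, size=4000)
    assert pdf_overlap(a, b) == pytest.approx(2 * 0.15865525393, abs=0.03)


@settings(deadline=None, max_examples=20, derandomize=True)
@given(
    shift=st.floats(-100, 100, allow_nan=False),
    scale=st.floats(0.1, 10.0),
    seed=st.integers(0, 10_000),
)
def test_overlap_symmetric_and_affine_invariant(shift, scale, seed):
    rng = np.random.default_rng(seed)
    a, b = rng.normal(size=40), rng.normal(1.0, 2.0, size=40)
    base = pdf_overlap(a, b)
    assert pdf_overlap(b, a) == pytest.approx(base, abs=1e-9)
    assert pdf_overlap(scale * a + shift, scale * b + shift) == pytest.approx(
        base, abs=0.02
    )


def test_overlap_degenerate_inputs():
    with pytest.raises(ValueError, match="constant"):
        pdf_overlap(np.ones(5), np.ones(5) * 2)
    # one constant sample is fine: treated as a narrow bump
    assert 0.0 <= pdf_overlap(np.ones(5), np.random.default_rng(0).normal(size=20)) <= 1.0
    with pytest.raises(ValueError, match="finite"):
        pdf_overlap(np.array([1.0, np.nan]), np.zeros(3))


# -- selection --------------------------------------------------------------


def _two_group(rng, n=20, p=50, effect_cols=(), effect=1.5):
    a = rng.normal(size=(n, p))
    b = rng.normal(size=(n, p))
    for j in effect_cols:
        b[:, j] += effect
    return _dataset(a), _dataset(b)


def test_selection_finds_planted_columns_and_ranks_by_overlap(rng):
    a, b = _two_group(rng, effect_cols=(10, 30), effect=2.5)
    trace = pointwise_ttest(a, b)
    sel = select_features(trace, a, b, alpha=0.005, overlap_max=0.8, k=5, min_sep=0.0)
    assert {10, 30} <= set(sel.selected_indices.tolist())
    assert np.all(np.diff(sel.selected_ovl) >= -1e-12)  # ascending OVL order


def test_selection_min_separation_suppresses_neighbours(rng):
    a, b = _two_group(rng, effect_cols=(10, 11, 12), effect=3.0)
    trace = pointwise_ttest(a, b)
    sel = select_features(trace, a, b, k=5, min_sep=2.5)
    wns = np.sort(sel.selected_wavenumbers)
    assert np.all(np.diff(wns) >= 2.5)


def test_selection_k_zero_is_empty_with_warning(rng):
    a, b = _two_group(rng, effect_cols=(5,), effect=3.0)
    trace = pointwise_ttest(a, b)
    with pytest.warns(UserWarning, match="empty"):
        sel = select_features(trace, a, b, k=0)
    assert sel.selected_indices.size == 0


def test_selection_is_deterministic(rng):
    a, b = _two_group(rng, effect_cols=(3, 7), effect=2.0)
    trace = pointwise_ttest(a, b)
    s1 = select_features(trace, a, b)
    s2 = select_features(trace, a, b)
    np.testing.assert_array_equal(s1.selected_indices, s2.selected_indices)


# -- subgroup traces --------------------------------------------------------


def test_vascular_invasion_effect_located_at_1012(planted_cohort):
    """The default clinical effect planted at 1012 cm⁻¹ dominates the
    vascular-invasion subgroup trace."""
    datasets, records = planted_cohort
    trace = subgroup_trace(datasets["PBMC"], records, "vascular_invasion")
    best = trace.grid.values[np.argmin(trace.p_values)]
    assert abs(best - 1012.0) <= 10.0


def test_subgroup_trace_errors_name_the_parameter(planted_cohort):
    datasets, records = planted_cohort
    with pytest.raises(ValueError, match="unknown clinical parameter"):
        subgroup_trace(datasets["PBMC"], records, "blood_type")
    # all-missing parameter: controls have no histology
    ctrl = datasets["PBMC"].subset(
        [s for s, l in zip(datasets["PBMC"].subject_ids, datasets["PBMC"].labels)
         if l == "control"]
    )
    with pytest.raises(ValueError, match="histology"):
        subgroup_trace(ctrl, records, "histology")


def test_permuted_strata_rarely_reach_bonferroni_significance(null_cohort):
    """With stratum labels assigned at random, the minimum p over all 2282
    wavenumbers should rarely cross 0.05/2282 (dependent-uniform minimum)."""
    datasets, records = null_cohort
    ds = datasets["PBMC"]
    cancer_ids = [s for s, l in zip(ds.subject_ids, ds.labels) if l == "cancer"]
    sub = ds.subset(cancer_ids)
    rng = np.random.default_rng(99)
    hits = 0
    for _ in range(50):
        perm = rng.permutation(len(cancer_ids))
        a = sub.subset([cancer_ids[i] for i in perm[:14]])
        b = sub.subset([cancer_ids[i] for i in perm[14:]])
        if pointwise_ttest(a, b).p_values.min() < 0.05 / 2282:
            hits += 1
    assert hits / 50 <= 0.10
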