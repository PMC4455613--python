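"""QDA scoring, component fusion, ROC construction and cut-off choice."""

import itertools

import numpy as np
import pytest
from scipy import stats

from irscreen import (
    choose_cutoff,
    combine_components,
    fit_qda,
    qda_score,
    roc_curve,
)
from irscreen.classify import evaluate_at_cutoff
from irscreen.grid import WavenumberGrid
from irscreen.spectra import SpectralDataset


def brute_force_auc(scores, labels):
    """Pairwise concordance with half-credit for ties (Mann-Whitney)."""
    pos = [s for s, l in zip(scores, labels) if l == "cancer"]
    neg = [s for s, l in zip(scores, labels) if l == "control"]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def _dataset(matrix, subject_ids, labels, component):
    matrix = np.asarray(matrix, dtype=float)
    grid = WavenumberGrid(700.0 + np.arange(matrix.shape[1], dtype=float))
    return SpectralDataset(matrix=matrix, grid=grid, subject_ids=subject_ids,
                           labels=np.asarray(labels, dtype=object), component=component)


# -- fusion -----------------------------------------------------------------


def test_combine_concatenates_and_drops_component_missing_subjects():
    ids = ["S1", "S2", "S3"]
    labels = ["cancer", "control", "cancer"]
    pbmc = _dataset(np.arange(9).reshape(3, 3), ids, labels, "PBMC")
    plasma = _dataset(np.arange(12).reshape(3, 4) + 100, ids, labels, "plasma")
    X, y, kept = combine_components(pbmc, plasma, np.arange(3), np.arange(4))
    assert X.shape == (3, 7)  # 3 PBMC + 4 plasma features
    assert kept == ids
    # a subject without plasma (e.g. hemolyzed sample) disappears from fusion
    plasma_partial = plasma.subset(["S1", "S3"])
    X2, y2, kept2 = combine_components(pbmc, plasma_partial, np.arange(3), np.arange(4))
    assert kept2 == ["S1", "S3"]
    assert list(y2) == ["cancer", "cancer"]
    # order is by subject id regardless of input order
    shuffled = pbmc.subset(["S3", "S1", "S2"])
    _, _, kept3 = combine_components(shuffled, plasma, np.arange(3), np.arange(4))
    assert kept3 == ids


def test_combine_empty_intersection_rejected():
    a = _dataset(np.zeros((2, 2)), ["S1", "S2"], ["cancer", "control"], "PBMC")
    b = _dataset(np.zeros((2, 2)), ["S3", "S4"], ["cancer", "control"], "plasma")
    with pytest.raises(ValueError, match="no subjects"):
        combine_components(a, b, [0], [0])


# -- QDA --------------------------------------------------------------------


def test_fit_recovers_means_at_large_n(rng):
    n = 500
    X = np.concatenate([rng.normal(0.0, 1.0, n), rng.normal(2.0, 1.0, n)])[:, None]
    y = np.array(["control"] * n + ["cancer"] * n, dtype=object)
    model = fit_qda(X, y)
    assert model.means["control"][0] == pytest.approx(0.0, abs=0.15)  # 3 sigma/sqrt(n)
    assert model.means["cancer"][0] == pytest.approx(2.0, abs=0.15)
    assert model.priors["cancer"] == 0.5


def test_identical_classes_score_is_prior_log_ratio(rng):
    base = rng.normal(size=(40, 2))
    X = np.vstack([base, base])
    y = np.array(["control"] * 40 + ["cancer"] * 40, dtype=object)
    model = fit_qda(X, y)
    scores = qda_score(model, rng.normal(size=(10, 2)))
    np.testing.assert_allclose(scores, np.log(0.5 / 0.5), atol=1e-9)


def test_more_features_than_subjects_rejected(rng):
    X = rng.normal(size=(8, 10))
    y = np.array(["control"] * 4 + ["cancer"] * 4, dtype=object)
    with pytest.raises(ValueError, match="fewer features"):
        fit_qda(X, y)


def test_score_zero_at_midpoint_under_symmetry(rng):
    n = 100
    X = np.concatenate([rng.normal(-1.0, 1.0, n), rng.normal(1.0, 1.0, n)])[:, None]
    X[:n] = -X[n:]  # exact mirror symmetry: equal sample covariances
    y = np.array(["control"] * n + ["cancer"] * n, dtype=object)
    model = fit_qda(X, y, shrinkage=0.0)
    midpoint = (model.means["control"] + model.means["cancer"]) / 2
    assert qda_score(model, midpoint) == pytest.approx(0.0, abs=1e-10)


def test_1d_score_matches_normal_logpdf_oracle(rng):
    X = np.concatenate([rng.normal(0.0, 1.0, 60), rng.normal(1.5, 2.0, 60)])[:, None]
    y = np.array(["control"] * 60 + ["cancer"] * 60, dtype=object)
    model = fit_qda(X, y, shrinkage=0.0)
    x = np.array([0.7])
    expected = stats.norm.logpdf(
        x[0], model.means["cancer"][0], np.sqrt(model.covariances["cancer"][0, 0])
    ) - stats.norm.logpdf(
        x[0], model.means["control"][0], np.sqrt(model.covariances["control"][0, 0])
    )
    assert qda_score(model, x) == pytest.approx(float(expected), abs=1e-10)


def test_equal_covariances_make_score_affine(rng):
    """When both classes share a covariance the quadratic terms cancel and the
    discriminant reduces to a linear (LDA) score."""
    cov = np.array([[2.0, 0.3], [0.3, 1.0]])
    mean_c = np.array([1.0, -1.0])
    model_cls = fit_qda(
        np.vstack([np.zeros((3, 2)), np.ones((3, 2))]),
        np.array(["control"] * 3 + ["cancer"] * 3, dtype=object),
        shrinkage=0.0,
    )
    model_cls.means = {"control": np.zeros(2), "cancer": mean_c}
    model_cls.covariances = {"control": cov, "cancer": cov}
    model_cls.priors = {"control": 0.5, "cancer": 0.5}
    grid_pts = np.array(list(itertools.product(np.linspace(-3, 3, 7), repeat=2)))
    scores = qda_score(model_cls, grid_pts)
    design = np.column_stack([grid_pts, np.ones(len(grid_pts))])
    coef, *_ = np.linalg.lstsq(design, scores, rcond=None)
    assert np.max(np.abs(design @ coef - scores)) < 1e-8


def test_score_invariant_to_consistent_feature_permutation(rng):
    X = rng.normal(size=(60, 4))
    X[30:] += [0.5, -0.5, 1.0, 0.0]
    y = np.array(["control"] * 30 + ["cancer"] * 30, dtype=object)
    perm = [2, 0, 3, 1]
    base = qda_score(fit_qda(X, y), X)
    permuted = qda_score(fit_qda(X[:, perm], y), X[:, perm])
    np.testing.assert_allclose(permuted, base, rtol=1e-8)


def test_sklearn_qda_agrees_on_posterior_log_ratio(rng):
    sklearn_qda = pytest.importorskip("sklearn.discriminant_analysis")
    X = rng.normal(size=(100, 3))
    X[50:] += [1.0, 0.5, -0.5]
    y = np.array(["control"] * 50 + ["cancer"] * 50, dtype=object)
    model = fit_qda(X, y, shrinkage=0.0)
    ours = qda_score(model, X)
    ref = sklearn_qda.QuadraticDiscriminantAnalysis(store_covariance=True).fit(X, y)
    lp = ref.predict_log_proba(X)
    theirs = lp[:, list(ref.classes_).index("cancer")] - lp[:, list(ref.classes_).index("control")]
    np.testing.assert_allclose(ours, theirs, rtol=1e-6, atol=1e-8)


# -- ROC --------------------------------------------------------------------


def test_auc_worked_example():
    scores = np.array([0.1, 0.35, 0.4, 0.8])
    labels = np.array(["control", "cancer", "control", "cancer"], dtype=object)
    roc = roc_curve(scores, labels)
    assert roc.auc == pytest.approx(0.75)  # 3 of 4 pos-neg pairs concordant
    assert brute_force_auc(scores, labels) == pytest.approx(0.75)


def test_auc_perfect_and_all_tied():
    labels = np.array(["control", "control", "cancer", "cancer"], dtype=object)
    assert roc_curve(np.array([0.0, 0.1, 1.0, 1.1]), labels).auc == pytest.approx(1.0)
    assert roc_curve(np.zeros(4), labels).auc == pytest.approx(0.5)


def test_auc_invariances(rng):
    scores = rng.normal(size=30)
    labels = np.array(["cancer" if v else "control" for v in rng.integers(0, 2, 30)],
                      dtype=object)
    if len(set(labels)) < 2:
        labels[0], labels[1] = "cancer", "control"
    base = roc_curve(scores, labels).auc
    monotone = roc_curve(np.exp(3.0 * scores), labels).auc
    assert monotone == pytest.approx(base, abs=1e-12)
    flipped = roc_curve(-scores, labels).auc
    assert base + flipped == pytest.approx(1.0, abs=1e-12)


def test_trapezoid_auc_equals_concordance_exhaustively():
    """Small-instance oracle: every score vector over {0,1,2} with balanced
    labels up to n=6 and every labelling of binary scores up to n=5."""
    for n in (2, 4, 6):
        labels = np.array(["control", "cancer"] * (n // 2), dtype=object)
        for scores in itertools.product((0, 1, 2), repeat=n):
            s = np.array(scores, dtype=float)
            assert roc_curve(s, labels).auc == pytest.approx(
                brute_force_auc(s, labels), abs=1e-12
            )
    for n in (3, 5):
        for scores in itertools.product((0, 1), repeat=n):
            for labels in itertools.product(("control", "cancer"), repeat=n):
                if len(set(labels)) < 2:
                    continue
                s = np.array(scores, dtype=float)
                l = np.array(labels, dtype=object)
                assert roc_curve(s, l).auc == pytest.approx(
                    brute_force_auc(s, l), abs=1e-12
                )


def test_sklearn_auc_cross_check(rng):
    sk_metrics = pytest.importorskip("sklearn.metrics")
    scores = rng.normal(size=50)
    labels = np.array(["cancer" if v else "control" for v in rng.integers(0, 2, 50)],
                      dtype=object)
    assert roc_curve(scores, labels).auc == pytest.approx(
        sk_metrics.roc_auc_score(labels == "cancer", scores), abs=1e-12
    )


# -- cut-off ----------------------------------------------------------------


def test_cutoff_tie_breaks_toward_sensitivity():
    scores = np.array([0.1, 0.35, 0.4, 0.8])
    labels = np.array(["control", "cancer", "control", "cancer"], dtype=object)
    roc = roc_curve(scores, labels)
    cutoff = choose_cutoff(roc)
    # two thresholds reach J = 0.5; the sensitivity-1.0 one (below 0.35) wins
    assert roc.sens_at_cutoff == 1.0 and roc.spec_at_cutoff == 0.5
    assert cutoff < 0.35
    sens, spec = evaluate_at_cutoff(scores, labels, cutoff)
    assert (sens, spec) == (1.0, 0.5)


def test_cutoff_perfect_separation_uses_gap_midpoint():
    labels = np.array(["control", "control", "cancer", "cancer"], dtype=object)
    roc = roc_curve(np.array([0.0, 0.2, 1.0, 1.4]), labels)
    cutoff = choose_cutoff(roc)
    assert cutoff == pytest.approx(0.6)  # midpoint of the separating gap
    assert roc.sens_at_cutoff == 1.0 and roc.spec_at_cutoff == 1.0


def test_cutoff_degenerate_curve_warns():
    labels = np.array(["control", "cancer"] * 3, dtype=object)
    roc = roc_curve(np.zeros(6), labels)
    with pytest.warns(UserWarning, match="chance"):
        choose_cutoff(roc)


def test_closest_topleft_criterion_runs():
    labels = np.array(["control", "cancer"] * 5, dtype=object)
    rng = np.random.default_rng(3)
    roc = roc_curve(rng.normal(size=10), labels)
    cutoff = choose_cutoff(roc, criterion="closest-topleft")
    assert np.isfinite(cutoff) or np.isinf(cutoff)
    with pytest.raises(ValueError, match="criterion"):
        choose_cutoff(roc, criterion="accuracy")
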