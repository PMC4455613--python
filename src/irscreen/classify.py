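"""Quadratic discriminant scoring, component fusion, ROC and cut-off choice.

The classifier models each class as a multivariate normal with its own
covariance; a subject's score is the log-density difference

    score(x) = delta_cancer(x) - delta_control(x),
    delta_c(x) = -1/2 ln|S_c| - 1/2 (x-m_c)' S_c^{-1} (x-m_c) + ln pi_c,

so higher scores are more cancer-like.  Covariances are shrunk toward a
scaled identity (S + lam * tr(S)/p * I) to stay positive-definite at small n.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .featsel import FeatureSelectionResult
from .spectra import SpectralDataset

log = logging.getLogger(__name__)

CLASS_ORDER = ("control", "cancer")


# ---------------------------------------------------------------------------
# Feature fusion across blood components
# ---------------------------------------------------------------------------


def combine_components(
    dataset_pbmc: SpectralDataset,
    dataset_plasma: SpectralDataset,
    features_pbmc: np.ndarray | FeatureSelectionResult,
    features_plasma: np.ndarray | FeatureSelectionResult,
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Concatenate each subject's selected PBMC features with plasma features.

    Only subjects present in both datasets are kept (e.g. hemolyzed plasma
    samples drop a subject); rows are ordered by subject id.  Returns
    (X, labels, subject_ids).
    """
    idx_pbmc = _as_indices(features_pbmc)
    idx_plasma = _as_indices(features_plasma)
    common = sorted(set(dataset_pbmc.subject_ids) & set(dataset_plasma.subject_ids))
    if not common:
        raise ValueError("no subjects present in both blood components")
    missing = sorted(
        set(dataset_pbmc.subject_ids) ^ set(dataset_plasma.subject_ids)
    )
    if missing:
        log.info("dropping %d subject(s) present in only one component: %s",
                 len(missing), ", ".join(missing))
    sub_pbmc = dataset_pbmc.subset(common)
    sub_plasma = dataset_plasma.subset(common)
    if not np.array_equal(sub_pbmc.labels, sub_plasma.labels):
        raise ValueError("class labels disagree between components")
    X = np.hstack([sub_pbmc.matrix[:, idx_pbmc], sub_plasma.matrix[:, idx_plasma]])
    return X, sub_pbmc.labels, common


def _as_indices(features) -> np.ndarray:
    if isinstance(features, FeatureSelectionResult):
        return features.selected_indices
    return np.asarray(features, dtype=int)


# ---------------------------------------------------------------------------
# QDA
# ---------------------------------------------------------------------------


@dataclass
class DiscriminantModel:
    """Per-class Gaussian model: means, shrunk covariances, priors."""

    means: dict[str, np.ndarray]
    covariances: dict[str, np.ndarray]
    priors: dict[str, float]
    shrinkage: float
    class_order: tuple[str, str] = CLASS_ORDER

    @property
    def n_features(self) -> int:
        return next(iter(self.means.values())).size


def fit_qda(
    X: np.ndarray,
    y: np.ndarray,
    shrinkage: float = 1e-6,
    priors: str = "empirical",
) -> DiscriminantModel:
    """Fit the two-class quadratic discriminant model.

    Requires more subjects than features in each class; otherwise raises
    with advice to select fewer features.  ``priors`` is ``"empirical"``
    (class frequencies) or ``"equal"``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=object)
    classes = set(y.tolist())
    if classes != set(CLASS_ORDER):
        raise ValueError(f"need both classes {CLASS_ORDER}, got {sorted(classes)}")
    n, p = X.shape
    means, covs, pri = {}, {}, {}
    for c in CLASS_ORDER:
        Xc = X[y == c]
        if Xc.shape[0] <= p:
            raise ValueError(
                f"class {c!r} has {Xc.shape[0]} subjects for {p} features; "
                "QDA needs n > p per class - select fewer features (smaller k)"
            )
        means[c] = Xc.mean(axis=0)
        cov = np.cov(Xc, rowvar=False, ddof=1).reshape(p, p)
        cov = cov + shrinkage * (np.trace(cov) / p) * np.eye(p)
        covs[c] = cov
        pri[c] = Xc.shape[0] / n if priors == "empirical" else 0.5
    return DiscriminantModel(means=means, covariances=covs, priors=pri, shrinkage=shrinkage)


def qda_score(model: DiscriminantModel, x: np.ndarray) -> np.ndarray | float:
    """Discriminant score(s); positive = more cancer-like.

    Accepts a single feature vector or an (n, p) matrix.
    """
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    X = np.atleast_2d(x)
    if X.shape[1] != model.n_features:
        raise ValueError(
            f"input has {X.shape[1]} features, model expects {model.n_features}"
        )
    deltas = {}
    for c in model.class_order:
        cov = model.covariances[c]
        sign, logdet = np.linalg.slogdet(cov)
        if sign <= 0:
            raise np.linalg.LinAlgError(f"covariance of class {c!r} is not PD")
        diff = X - model.means[c]
        maha = np.einsum("ij,ij->i", diff, np.linalg.solve(cov, diff.T).T)
        deltas[c] = -0.5 * logdet - 0.5 * maha + np.log(model.priors[c])
    scores = deltas["cancer"] - deltas["control"]
    return float(scores[0]) if single else scores


# ---------------------------------------------------------------------------
# ROC
# ---------------------------------------------------------------------------


@dataclass
class RocCurve:
    """ROC over all midpoint thresholds, with trapezoidal AUC.

    ``thresholds`` is descending and starts at +inf and ends at -inf; a
    subject is called cancer when its score is >= the threshold, so
    sensitivity is non-decreasing along the array.
    """

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    chosen_cutoff: float | None = None
    sens_at_cutoff: float | None = None
    spec_at_cutoff: float | None = None

    def at_threshold(self, threshold: float) -> tuple[float, float]:
        """(sensitivity, specificity) of the rule score >= threshold."""
        i = int(np.argmin(np.abs(self.thresholds - threshold)))
        return float(self.sensitivity[i]), float(self.specificity[i])


def roc_curve(scores: np.ndarray, labels: np.ndarray) -> RocCurve:
    """Build the ROC of the rule "call cancer iff score >= t".

    Thresholds are +inf, the midpoints between consecutive distinct sorted
    scores, and -inf; the AUC is the trapezoidal integral, equivalent to
    pairwise concordance with ties counting one half.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=object)
    pos = scores[labels == "cancer"]
    neg = scores[labels == "control"]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("ROC needs both classes present")
    distinct = np.unique(scores)
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    thresholds = np.concatenate(([np.inf], mids[::-1], [-np.inf]))
    sens = np.array([(pos >= t).mean() for t in thresholds])
    spec = np.array([(neg < t).mean() for t in thresholds])
    fpr = 1.0 - spec
    auc = float(np.trapezoid(sens, fpr))
    return RocCurve(thresholds=thresholds, sensitivity=sens, specificity=spec, auc=auc)


def evaluate_at_cutoff(
    scores: np.ndarray, labels: np.ndarray, cutoff: float
) -> tuple[float, float]:
    """(sensitivity, specificity) of score >= cutoff on an arbitrary sample."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=object)
    pos = scores[labels == "cancer"]
    neg = scores[labels == "control"]
    sens = float((pos >= cutoff).mean()) if pos.size else np.nan
    spec = float((neg < cutoff).mean()) if neg.size else np.nan
    return sens, spec


def choose_cutoff(roc: RocCurve, criterion: str = "youden") -> float:
    """Pick the operating threshold and record it on the curve.

    ``youden`` maximizes sensitivity + specificity - 1; ``closest-topleft``
    minimizes the Euclidean distance to the (0, 1) corner.  Ties are broken
    toward higher sensitivity (screening favors catching cases), then toward
    the lower threshold.
    """
    if criterion == "youden":
        objective = roc.sensitivity + roc.specificity - 1.0
    elif criterion == "closest-topleft":
        objective = -np.hypot(1.0 - roc.sensitivity, 1.0 - roc.specificity)
    else:
        raise ValueError(f"unknown cutoff criterion {criterion!r}")
    best = objective.max()
    if criterion == "youden" and best <= 0:
        warnings.warn("ROC is at chance level everywhere; cutoff is arbitrary",
                      stacklevel=2)
    tied = np.flatnonzero(np.isclose(objective, best))
    tied = tied[roc.sensitivity[tied] == roc.sensitivity[tied].max()]
    idx = tied[np.argmin(roc.thresholds[tied])]
    roc.chosen_cutoff = float(roc.thresholds[idx])
    roc.sens_at_cutoff = float(roc.sensitivity[idx])
    roc.spec_at_cutoff = float(roc.specificity[idx])
    return roc.chosen_cutoff
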