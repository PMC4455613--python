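"""Per-wavenumber two-group statistics and feature selection.

Two screening criteria are applied to every wavenumber of the preprocessed
(second-derivative) spectra: a two-sample t-test against a significance
level (default P < 0.005), and the overlapping coefficient (OVL) of the two
classes' kernel-density estimates, which measures how separable the feature
actually is.  Candidates passing both are ranked by ascending OVL and capped
so the downstream quadratic classifier keeps many more subjects than
features.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .grid import WavenumberGrid
from .spectra import SpectralDataset
from .synth import SubjectRecord

log = logging.getLogger(__name__)

_TINY_P = np.finfo(float).tiny


@dataclass
class PValueTrace:
    """Per-wavenumber two-sided p-values and t statistics."""

    grid: WavenumberGrid
    p_values: np.ndarray
    t_stats: np.ndarray
    n_a: int
    n_b: int

    def __post_init__(self) -> None:
        if self.p_values.shape != (len(self.grid),) or self.t_stats.shape != (len(self.grid),):
            raise ValueError("trace length must match grid length")


def pointwise_ttest(
    dataset_a: SpectralDataset, dataset_b: SpectralDataset, pooled: bool = False
) -> PValueTrace:
    """Two-sample t-test at every wavenumber (Welch by default).

    ``pooled=True`` gives the classical equal-variance Student statistic.
    Wavenumbers where both groups are exactly constant get t = 0, p = 1 when
    the constants agree and p = tiny when they differ.
    """
    if dataset_a.grid != dataset_b.grid:
        raise ValueError("datasets must share a wavenumber grid")
    a, b = dataset_a.matrix, dataset_b.matrix
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("each group needs at least 2 subjects")
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = stats.ttest_ind(a, b, axis=0, equal_var=pooled)
    t = np.asarray(t, dtype=float)
    p = np.asarray(p, dtype=float)
    degenerate = ~np.isfinite(t)
    if degenerate.any():
        same = np.isclose(a.mean(axis=0), b.mean(axis=0))
        t[degenerate & same] = 0.0
        p[degenerate & same] = 1.0
        t[degenerate & ~same] = np.inf
        p[degenerate & ~same] = _TINY_P
    p = np.clip(p, _TINY_P, 1.0)
    return PValueTrace(
        grid=dataset_a.grid, p_values=p, t_stats=t, n_a=a.shape[0], n_b=b.shape[0]
    )


# ---------------------------------------------------------------------------
# Overlapping coefficient
# ---------------------------------------------------------------------------


def _silverman_bw(sample: np.ndarray) -> float:
    # scipy's 'silverman' rule for d=1: (3n/4)^(-1/5) * sample std
    n = sample.size
    return float(np.std(sample, ddof=1) * (3.0 * n / 4.0) ** (-0.2))


def pdf_overlap(samples_a: np.ndarray, samples_b: np.ndarray) -> float:
    """Overlapping coefficient ∫ min(f̂_A, f̂_B) of two Gaussian KDEs.

    Silverman-bandwidth kernel density estimates are integrated numerically
    over the pooled range extended by three bandwidths; the result is
    clipped to [0, 1].  1 means indistinguishable distributions, 0 disjoint
    supports.  A sample that is exactly constant borrows the other sample's
    bandwidth; two constant samples are degenerate and raise.
    """
    a = np.asarray(samples_a, dtype=float).ravel()
    b = np.asarray(samples_b, dtype=float).ravel()
    if a.size < 2 or b.size < 2 or not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("each sample needs >= 2 finite values")
    bw_a, bw_b = _silverman_bw(a), _silverman_bw(b)
    if bw_a == 0.0 and bw_b == 0.0:
        raise ValueError("both samples are constant; overlap is undefined")
    bw_a = bw_a or bw_b
    bw_b = bw_b or bw_a
    pad = 3.0 * max(bw_a, bw_b)
    grid = np.linspace(min(a.min(), b.min()) - pad, max(a.max(), b.max()) + pad, 512)

    def density(sample: np.ndarray, bw: float) -> np.ndarray:
        if np.std(sample) > 0:
            return stats.gaussian_kde(sample, bw_method="silverman")(grid)
        # constant sample: a single Gaussian bump with the borrowed bandwidth
        return stats.norm.pdf(grid, loc=sample[0], scale=bw)

    overlap = np.trapezoid(np.minimum(density(a, bw_a), density(b, bw_b)), grid)
    return float(np.clip(overlap, 0.0, 1.0))


# ---------------------------------------------------------------------------
# Selection
# ---------------------------------------------------------------------------


@dataclass
class FeatureSelectionResult:
    """Selected wavenumber indices with their ranking statistics.

    Features are ranked by ascending OVL (ties: ascending p, then ascending
    wavenumber); ``candidate_*`` arrays cover everything that passed the
    p-value criterion, before the OVL threshold and cap.
    """

    grid: WavenumberGrid
    selected_indices: np.ndarray
    selected_p: np.ndarray
    selected_ovl: np.ndarray
    alpha: float
    overlap_max: float
    k: int
    candidate_indices: np.ndarray
    candidate_ovl: np.ndarray

    @property
    def selected_wavenumbers(self) -> np.ndarray:
        return self.grid.values[self.selected_indices]


def select_features(
    trace: PValueTrace,
    dataset_a: SpectralDataset,
    dataset_b: SpectralDataset,
    alpha: float = 0.005,
    overlap_max: float = 0.8,
    k: int = 10,
    min_sep: float = 8.0,
) -> FeatureSelectionResult:
    """Apply both screening criteria and return the capped feature set.

    ``min_sep`` (cm⁻¹) greedily suppresses near-duplicate picks inside one
    absorption band: after ranking, a candidate closer than ``min_sep`` to an
    already-kept wavenumber is skipped.  An empty selection is allowed and
    warned about.
    """
    candidates = np.flatnonzero(trace.p_values < alpha)
    ovl = np.array(
        [
            pdf_overlap(dataset_a.matrix[:, j], dataset_b.matrix[:, j])
            for j in candidates
        ]
    )
    passing = candidates[ovl <= overlap_max] if candidates.size else candidates
    passing_ovl = ovl[ovl <= overlap_max] if candidates.size else ovl
    order = np.lexsort(
        (trace.grid.values[passing], trace.p_values[passing], passing_ovl)
    ) if passing.size else np.array([], dtype=int)

    selected: list[int] = []
    for idx in passing[order] if k > 0 else []:
        wn = trace.grid.values[idx]
        if any(abs(wn - trace.grid.values[j]) < min_sep for j in selected):
            continue
        selected.append(int(idx))
        if len(selected) >= k:
            break
    if not selected:
        warnings.warn("feature selection returned an empty set", stacklevel=2)
    sel = np.array(selected, dtype=int)
    return FeatureSelectionResult(
        grid=trace.grid,
        selected_indices=sel,
        selected_p=trace.p_values[sel],
        selected_ovl=np.array(
            [passing_ovl[np.flatnonzero(passing == j)[0]] for j in sel]
        ),
        alpha=alpha,
        overlap_max=overlap_max,
        k=k,
        candidate_indices=candidates,
        candidate_ovl=ovl,
    )


# ---------------------------------------------------------------------------
# Clinical subgroup traces
# ---------------------------------------------------------------------------

_SUBGROUP_SPLITS = {
    "mass_size": (
        lambda r: None if r.mass_size_mm is None else r.mass_size_mm > 20.0,
        "> 20 mm vs <= 20 mm",
    ),
    "n_masses": (
        lambda r: None if r.n_masses is None else r.n_masses >= 2,
        "multiple vs single mass",
    ),
    "stage": (
        lambda r: {"I": False, "II": True}.get(r.stage),
        "stage II vs stage I",
    ),
    "histology": (
        lambda r: {"IDC": False, "ILC": True}.get(r.histology),
        "ILC vs IDC",
    ),
    "vascular_invasion": (lambda r: r.vascular_invasion, "positive vs negative"),
    "node_involvement": (lambda r: r.node_involvement, "positive vs negative"),
}


def subgroup_trace(
    dataset: SpectralDataset,
    records: list[SubjectRecord],
    parameter: str,
    pooled: bool = False,
) -> PValueTrace:
    """Pointwise t-test between two clinical strata within the cancer group.

    Subjects with a missing value of the parameter are dropped pairwise.
    Raises (naming the parameter) when either stratum has fewer than 2
    subjects.
    """
    if parameter not in _SUBGROUP_SPLITS:
        raise ValueError(
            f"unknown clinical parameter {parameter!r}; "
            f"choose from {sorted(_SUBGROUP_SPLITS)}"
        )
    predicate, _ = _SUBGROUP_SPLITS[parameter]
    by_id = {r.subject_id: r for r in records}
    low, high = [], []
    for sid, label in zip(dataset.subject_ids, dataset.labels):
        record = by_id.get(sid)
        if label != "cancer" or record is None:
            continue
        value = predicate(record)
        if value is None:
            continue
        (high if value else low).append(sid)
    if len(low) < 2 or len(high) < 2:
        raise ValueError(
            f"clinical parameter {parameter!r}: stratum too small "
            f"({len(low)} vs {len(high)} subjects after dropping missing values)"
        )
    return pointwise_ttest(dataset.subset(low), dataset.subset(high), pooled=pooled)
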