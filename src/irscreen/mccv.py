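"""Monte Carlo cross-validation of the select → fuse → fit → cutoff chain.

Each repetition draws a fresh stratified subject-level train/validation
split, runs feature selection on the training subjects only (by default),
fuses the selected PBMC and plasma features, fits the quadratic
discriminant, picks the operating cut-off on the training ROC, and then
evaluates both sets at that fixed cut-off.  Aggregates are means and SDs
(and percentiles) over repetitions.

Selecting features on all subjects before splitting leaks validation
information into the model; the ``selection_in_loop=False`` escape hatch
exists precisely so the inflation can be demonstrated.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classify import (
    RocCurve,
    choose_cutoff,
    combine_components,
    evaluate_at_cutoff,
    fit_qda,
    qda_score,
    roc_curve,
)
from .featsel import FeatureSelectionResult, pointwise_ttest, select_features
from .spectra import SpectralDataset

log = logging.getLogger(__name__)


@dataclass
class MccvConfig:
    n_repetitions: int = 500
    train_fraction: float = 0.7
    stratified: bool = True
    seed: int = 0
    selection_in_loop: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.n_repetitions < 1:
            raise ValueError("n_repetitions must be >= 1")


@dataclass
class FeatselParams:
    alpha: float = 0.005
    overlap_max: float = 0.8
    k: int = 10
    min_sep: float = 8.0
    pooled: bool = False


@dataclass
class ClassifyParams:
    shrinkage: float = 1e-6
    priors: str = "empirical"
    criterion: str = "youden"


@dataclass
class MccvSummary:
    """Per-repetition results plus recomputable aggregates.

    ``per_repetition`` columns: train_auc, val_auc, train_sens, train_spec,
    val_sens, val_spec, n_features, cutoff.  ``aggregates`` holds the mean,
    SD and 2.5/97.5 percentiles of each column.
    """

    per_repetition: pd.DataFrame
    n_skipped: int
    train_curves: list[RocCurve] = field(default_factory=list, repr=False)
    val_curves: list[RocCurve] = field(default_factory=list, repr=False)

    @property
    def aggregates(self) -> pd.DataFrame:
        stats = self.per_repetition.agg(["mean", "std"]).T
        quantiles = self.per_repetition.quantile([0.025, 0.975]).T
        quantiles.columns = ["p2.5", "p97.5"]
        return pd.concat([stats, quantiles], axis=1)


def split_subjects(
    subject_ids: list[str],
    labels: np.ndarray,
    config: MccvConfig,
    stream: np.random.Generator,
) -> tuple[list[str], list[str]]:
    """Random subject-level train/validation partition.

    Stratified splits preserve the class ratio to within one subject and
    guarantee at least 2 training and 1 validation subject per class.
    """
    subject_ids = list(subject_ids)
    labels = np.asarray(labels, dtype=object)
    train: list[str] = []
    val: list[str] = []
    if config.stratified:
        for c in np.unique(labels):
            members = [s for s, l in zip(subject_ids, labels) if l == c]
            if len(members) < 3:
                raise ValueError(f"class {c!r} too small to stratify ({len(members)})")
            n_train = int(round(config.train_fraction * len(members)))
            n_train = min(max(n_train, 2), len(members) - 1)
            perm = stream.permutation(len(members))
            train += [members[i] for i in perm[:n_train]]
            val += [members[i] for i in perm[n_train:]]
    else:
        n_train = int(round(config.train_fraction * len(subject_ids)))
        n_train = min(max(n_train, 2), len(subject_ids) - 1)
        perm = stream.permutation(len(subject_ids))
        train = [subject_ids[i] for i in perm[:n_train]]
        val = [subject_ids[i] for i in perm[n_train:]]
    return sorted(train), sorted(val)


def _select_for(
    dataset: SpectralDataset, params: FeatselParams
) -> FeatureSelectionResult:
    ctrl, canc = dataset.split_by_label()
    trace = pointwise_ttest(ctrl, canc, pooled=params.pooled)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # empty selections are expected under the null
        return select_features(
            trace,
            ctrl,
            canc,
            alpha=params.alpha,
            overlap_max=params.overlap_max,
            k=params.k,
            min_sep=params.min_sep,
        )


def _rank_merge_cap(
    sel_pbmc: FeatureSelectionResult,
    sel_plasma: FeatureSelectionResult,
    p_max: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Cap the fused feature count at p_max, keeping best-ranked features.

    Features from both components are merged by their selection rank key
    (OVL, then p, then wavenumber) and the weakest are dropped until the
    quadratic model is estimable on the training class sizes.
    """
    entries = []
    for comp, sel in (("PBMC", sel_pbmc), ("plasma", sel_plasma)):
        for i, idx in enumerate(sel.selected_indices):
            entries.append(
                (sel.selected_ovl[i], sel.selected_p[i], sel.grid.values[idx], comp, idx)
            )
    entries.sort()
    kept = entries[:p_max]
    pbmc = np.array(sorted(e[4] for e in kept if e[3] == "PBMC"), dtype=int)
    plasma = np.array(sorted(e[4] for e in kept if e[3] == "plasma"), dtype=int)
    return pbmc, plasma


def mccv_run(
    dataset_pbmc: SpectralDataset,
    dataset_plasma: SpectralDataset,
    featsel_params: FeatselParams | None = None,
    classify_params: ClassifyParams | None = None,
    config: MccvConfig | None = None,
    _selection_audit: list | None = None,
) -> MccvSummary:
    """Run the full Monte Carlo cross-validation.

    Subjects missing either blood component are excluded before splitting.
    A repetition whose fused feature set comes out empty is skipped and
    counted; the run fails if more than half the repetitions are skipped.
    ``_selection_audit``, when given a list, records the subject ids passed
    to feature selection in each repetition (test instrumentation).
    """
    featsel_params = featsel_params or FeatselParams()
    classify_params = classify_params or ClassifyParams()
    config = config or MccvConfig()

    common = sorted(set(dataset_pbmc.subject_ids) & set(dataset_plasma.subject_ids))
    if not common:
        raise ValueError("no subjects with both blood components")
    ds_pbmc = dataset_pbmc.subset(common)
    ds_plasma = dataset_plasma.subset(common)
    labels = ds_pbmc.labels

    preselected = None
    if not config.selection_in_loop:
        preselected = (_select_for(ds_pbmc, featsel_params),
                       _select_for(ds_plasma, featsel_params))

    children = np.random.SeedSequence(config.seed).spawn(config.n_repetitions)
    rows = []
    train_curves: list[RocCurve] = []
    val_curves: list[RocCurve] = []
    n_skipped = 0
    for child in children:
        stream = np.random.default_rng(child)
        train_ids, val_ids = split_subjects(common, labels, config, stream)
        if config.selection_in_loop:
            sel_pbmc = _select_for(ds_pbmc.subset(train_ids), featsel_params)
            sel_plasma = _select_for(ds_plasma.subset(train_ids), featsel_params)
            if _selection_audit is not None:
                _selection_audit.append(set(train_ids))
        else:
            sel_pbmc, sel_plasma = preselected
        train_labels = ds_pbmc.subset(train_ids).labels
        n_min = min(
            int((train_labels == "control").sum()), int((train_labels == "cancer").sum())
        )
        idx_pbmc, idx_plasma = _rank_merge_cap(sel_pbmc, sel_plasma, n_min - 1)
        if idx_pbmc.size + idx_plasma.size == 0:
            n_skipped += 1
            continue
        X_train, y_train, _ = combine_components(
            ds_pbmc.subset(train_ids), ds_plasma.subset(train_ids), idx_pbmc, idx_plasma
        )
        X_val, y_val, _ = combine_components(
            ds_pbmc.subset(val_ids), ds_plasma.subset(val_ids), idx_pbmc, idx_plasma
        )
        try:
            model = fit_qda(
                X_train, y_train,
                shrinkage=classify_params.shrinkage, priors=classify_params.priors,
            )
            train_scores = qda_score(model, X_train)
            val_scores = qda_score(model, X_val)
        except np.linalg.LinAlgError:
            n_skipped += 1
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # chance-level ROCs warn under the null
            train_roc = roc_curve(train_scores, y_train)
            cutoff = choose_cutoff(train_roc, criterion=classify_params.criterion)
        val_roc = roc_curve(val_scores, y_val)
        val_sens, val_spec = evaluate_at_cutoff(val_scores, y_val, cutoff)
        rows.append(
            {
                "train_auc": train_roc.auc,
                "val_auc": val_roc.auc,
                "train_sens": train_roc.sens_at_cutoff,
                "train_spec": train_roc.spec_at_cutoff,
                "val_sens": val_sens,
                "val_spec": val_spec,
                "n_features": idx_pbmc.size + idx_plasma.size,
                "cutoff": cutoff,
            }
        )
        train_curves.append(train_roc)
        val_curves.append(val_roc)
    if n_skipped > 0.5 * config.n_repetitions:
        raise RuntimeError(
            f"{n_skipped}/{config.n_repetitions} repetitions had no usable features; "
            "the selection criteria are too strict for this data"
        )
    if n_skipped:
        log.info("%d/%d repetitions skipped (empty feature set)",
                 n_skipped, config.n_repetitions)
    return MccvSummary(
        per_repetition=pd.DataFrame(rows),
        n_skipped=n_skipped,
        train_curves=train_curves,
        val_curves=val_curves,
    )


def aggregate_roc(
    curves: list[RocCurve], n_grid: int = 101
) -> tuple[np.ndarray, np.ndarray]:
    """Vertically average ROC curves: mean sensitivity on a fixed FPR grid."""
    if not curves:
        raise ValueError("no ROC curves to aggregate")
    grid = np.linspace(0.0, 1.0, n_grid)
    stack = []
    for c in curves:
        fpr = 1.0 - c.specificity
        order = np.argsort(fpr, kind="stable")
        stack.append(np.interp(grid, fpr[order], c.sensitivity[order]))
    return grid, np.mean(stack, axis=0)
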