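"""End-to-end orchestration: simulate/read → preprocess → select → classify → MC-CV.

One master seed governs the whole run: the cohort simulation and the
Monte Carlo cross-validation draw from named substreams spawned from it, so
a single integer reproduces every number in the report.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as spectra_io
from .bands import annotate_bands
from .classify import choose_cutoff, combine_components, fit_qda, qda_score, roc_curve
from .featsel import pointwise_ttest, select_features
from .mccv import (
    ClassifyParams,
    FeatselParams,
    MccvConfig,
    MccvSummary,
    _rank_merge_cap,
    aggregate_roc,
    mccv_run,
)
from .preprocess import PreprocessParams, preprocess_pipeline
from .synth import CohortConfig, simulate_cohort

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything a pipeline run needs; every field has a usable default."""

    outdir: str = "irscreen_run"
    seed: int = 0
    #: When set, simulate this cohort; otherwise read spectra/metadata paths.
    synth: CohortConfig | None = field(default_factory=CohortConfig)
    spectra_path: str | None = None
    metadata_path: str | None = None
    preprocess: PreprocessParams = field(default_factory=PreprocessParams)
    featsel: FeatselParams = field(default_factory=FeatselParams)
    classify: ClassifyParams = field(default_factory=ClassifyParams)
    mccv: MccvConfig = field(default_factory=MccvConfig)
    plots: bool = False


@dataclass
class RunReport:
    """Human- and machine-readable end-of-run summary."""

    seed: int
    qc_counts: dict[str, int]
    n_subjects: dict[str, int]
    dropped_subjects: dict[str, list[str]]
    selected_features: dict[str, list[dict]]
    full_fit: dict[str, float]
    mccv_aggregates: dict[str, dict[str, float]]
    n_skipped: int
    config: dict

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, default=str)

    def to_text(self) -> str:
        lines = [
            "irscreen pipeline report",
            f"seed: {self.seed}",
            f"QC verdicts: {self.qc_counts}",
            f"subjects per component: {self.n_subjects}",
        ]
        for comp, feats in self.selected_features.items():
            lines.append(f"selected features ({comp}):")
            for f in feats:
                lines.append(
                    f"  {f['wavenumber']:8.1f} cm^-1  p={f['p']:.3g}  "
                    f"OVL={f['ovl']:.3f}  {f['assignment']}"
                )
        ff = self.full_fit
        lines.append(
            f"full-data fit: AUC={ff['auc']:.3f}  "
            f"sens={ff['sens']:.2f} spec={ff['spec']:.2f} at cutoff {ff['cutoff']:.3g}"
        )
        for split in ("train", "val"):
            agg = self.mccv_aggregates[f"{split}_auc"]
            lines.append(
                f"MC-CV {split} AUC: {agg['mean']:.3f} ± {agg['std']:.3f} "
                f"[{agg['p2.5']:.3f}, {agg['p97.5']:.3f}]"
            )
        lines.append(
            "MC-CV validation sens/spec at training cutoff: "
            f"{self.mccv_aggregates['val_sens']['mean']:.2f} / "
            f"{self.mccv_aggregates['val_spec']['mean']:.2f}"
        )
        if self.n_skipped:
            lines.append(f"repetitions skipped (no features): {self.n_skipped}")
        return "\n".join(lines)


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the whole analysis and persist intermediates under ``outdir``."""
    if config.synth is None and not (config.spectra_path and config.metadata_path):
        raise ValueError("config needs either synth settings or input paths")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = np.random.SeedSequence(config.seed).generate_state(2) % (2**31)

    if config.synth is not None:
        synth_config = dataclasses.replace(config.synth, seed=int(seeds[0]))
        spectra, records = simulate_cohort(synth_config)
        spectra_io.write_metadata(records, outdir / "metadata.csv")
    else:
        spectra = spectra_io.read_csv_matrix(config.spectra_path)
        records = spectra_io.read_metadata(config.metadata_path)

    group_of = {r.subject_id: r.group for r in records}
    result = preprocess_pipeline(spectra, group_of, config.preprocess)
    result.qc.table.to_csv(outdir / "qc_report.csv", index=False)
    for comp, ds in result.datasets.items():
        frame = pd.DataFrame(ds.matrix, index=ds.subject_ids, columns=ds.grid.values)
        frame.to_csv(outdir / f"dataset_{comp}.csv")
    if set(result.datasets) != {"PBMC", "plasma"}:
        raise RuntimeError("pipeline needs both PBMC and plasma datasets after QC")

    selections = {}
    traces = {}
    for comp, ds in result.datasets.items():
        ctrl, canc = ds.split_by_label()
        trace = pointwise_ttest(ctrl, canc, pooled=config.featsel.pooled)
        traces[comp] = trace
        selections[comp] = select_features(
            trace, ctrl, canc,
            alpha=config.featsel.alpha,
            overlap_max=config.featsel.overlap_max,
            k=config.featsel.k,
            min_sep=config.featsel.min_sep,
        )
        pd.DataFrame(
            {"wavenumber": trace.grid.values, "t": trace.t_stats, "p": trace.p_values}
        ).to_csv(outdir / f"trace_{comp}.csv", index=False)

    # cap the fused feature count so the per-class covariances stay estimable
    common = sorted(
        set(result.datasets["PBMC"].subject_ids)
        & set(result.datasets["plasma"].subject_ids)
    )
    common_labels = result.datasets["PBMC"].subset(common).labels
    n_min = min(
        int((common_labels == "control").sum()), int((common_labels == "cancer").sum())
    )
    idx_pbmc, idx_plasma = _rank_merge_cap(
        selections["PBMC"], selections["plasma"], n_min - 1
    )
    X, y, fused_ids = combine_components(
        result.datasets["PBMC"], result.datasets["plasma"], idx_pbmc, idx_plasma
    )
    model = fit_qda(X, y, shrinkage=config.classify.shrinkage, priors=config.classify.priors)
    scores = qda_score(model, X)
    full_roc = roc_curve(scores, y)
    cutoff = choose_cutoff(full_roc, criterion=config.classify.criterion)
    pd.DataFrame({"subject_id": fused_ids, "label": y, "score": scores}).to_csv(
        outdir / "scores.csv", index=False
    )

    summary = mccv_run(
        result.datasets["PBMC"], result.datasets["plasma"],
        featsel_params=config.featsel,
        classify_params=config.classify,
        config=dataclasses.replace(config.mccv, seed=int(seeds[1])),
    )
    summary.per_repetition.to_csv(outdir / "mccv_repetitions.csv", index=False)
    for split, curves in (("train", summary.train_curves), ("val", summary.val_curves)):
        fpr, tpr = aggregate_roc(curves)
        pd.DataFrame({"fpr": fpr, "mean_sensitivity": tpr}).to_csv(
            outdir / f"mccv_roc_{split}.csv", index=False
        )

    selected_features = {
        comp: [
            {
                "wavenumber": float(wn),
                "p": float(p),
                "ovl": float(ovl),
                "assignment": ann.assignment,
            }
            for wn, p, ovl, ann in zip(
                sel.selected_wavenumbers,
                sel.selected_p,
                sel.selected_ovl,
                annotate_bands(sel.selected_wavenumbers),
            )
        ]
        for comp, sel in selections.items()
    }
    report = RunReport(
        seed=config.seed,
        qc_counts=result.qc.counts,
        n_subjects={c: ds.n_subjects for c, ds in result.datasets.items()},
        dropped_subjects=result.dropped_subjects,
        selected_features=selected_features,
        full_fit={
            "auc": full_roc.auc,
            "sens": full_roc.sens_at_cutoff,
            "spec": full_roc.spec_at_cutoff,
            "cutoff": cutoff,
            "n_fused": len(fused_ids),
        },
        mccv_aggregates={
            col: row.to_dict() for col, row in summary.aggregates.iterrows()
        },
        n_skipped=summary.n_skipped,
        config=_config_dict(config),
    )
    (outdir / "report.json").write_text(report.to_json())
    (outdir / "report.txt").write_text(report.to_text() + "\n")
    if config.plots:
        _write_plots(outdir, traces, summary)
    return report


def _config_dict(config: RunConfig) -> dict:
    d = dataclasses.asdict(config)
    return json.loads(json.dumps(d, default=str))


def _write_plots(outdir: Path, traces, summary: MccvSummary) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 4))
    for comp, trace in traces.items():
        ax.semilogy(trace.grid.values, trace.p_values, label=comp, lw=0.8)
    ax.axhline(0.05, color="k", lw=1, label="P = 0.05")
    ax.set_xlabel("wavenumber (cm$^{-1}$)")
    ax.set_ylabel("p-value")
    ax.invert_xaxis()
    ax.legend()
    fig.tight_layout()
    fig.savefig(outdir / "pvalue_trace.png", dpi=150)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(5, 5))
    for split, curves, style in (
        ("training", summary.train_curves, "-"),
        ("validation", summary.val_curves, "--"),
    ):
        fpr, tpr = aggregate_roc(curves)
        ax.plot(fpr, tpr, style, label=split)
    ax.plot([0, 1], [0, 1], ":", color="gray", lw=1)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.legend()
    fig.tight_layout()
    fig.savefig(outdir / "roc.png", dpi=150)
    plt.close(fig)
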