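"""In-memory containers for single spectra and preprocessed datasets."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .grid import WavenumberGrid

COMPONENTS = ("PBMC", "plasma")


@dataclass
class Spectrum:
    """One absorption measurement: absorbance values on a wavenumber grid.

    ``subject_id`` / ``component`` / ``replicate`` identify the measurement;
    ``component`` is the blood fraction the dried film was prepared from.
    """

    grid: WavenumberGrid
    absorbance: np.ndarray
    subject_id: str
    component: str
    replicate: int = 1

    def __post_init__(self) -> None:
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.absorbance.shape != (len(self.grid),):
            raise ValueError(
                f"absorbance length {self.absorbance.size} != grid length {len(self.grid)}"
            )
        if not np.all(np.isfinite(self.absorbance)):
            raise ValueError("absorbance must be finite")
        if self.component not in COMPONENTS:
            raise ValueError(f"unknown blood component {self.component!r}")
        if self.replicate < 1:
            raise ValueError("replicate index starts at 1")

    def with_values(self, values: np.ndarray, grid: WavenumberGrid | None = None) -> "Spectrum":
        """Copy of this spectrum with new values (and optionally a new grid)."""
        return Spectrum(
            grid=grid if grid is not None else self.grid,
            absorbance=np.asarray(values, dtype=float),
            subject_id=self.subject_id,
            component=self.component,
            replicate=self.replicate,
        )


@dataclass
class SpectralDataset:
    """Subjects × wavenumbers matrix after preprocessing and replicate averaging.

    Rows align with ``subject_ids`` and ``labels``; labels are the two-class
    screening contrast ``"cancer"`` vs ``"control"`` (benign + healthy merged).
    """

    matrix: np.ndarray
    grid: WavenumberGrid
    subject_ids: list[str]
    labels: np.ndarray
    component: str

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.labels = np.asarray(self.labels, dtype=object)
        n, p = self.matrix.shape
        if len(self.subject_ids) != n or self.labels.size != n:
            raise ValueError("row count, subject_ids and labels must align")
        if p != len(self.grid):
            raise ValueError("column count must equal grid length")

    @property
    def n_subjects(self) -> int:
        return self.matrix.shape[0]

    def subset(self, subject_ids: list[str]) -> "SpectralDataset":
        """Row subset in the given subject order."""
        index = {s: i for i, s in enumerate(self.subject_ids)}
        rows = [index[s] for s in subject_ids]
        return SpectralDataset(
            matrix=self.matrix[rows],
            grid=self.grid,
            subject_ids=list(subject_ids),
            labels=self.labels[rows],
            component=self.component,
        )

    def split_by_label(self) -> tuple["SpectralDataset", "SpectralDataset"]:
        """(control subset, cancer subset)."""
        ctrl = [s for s, l in zip(self.subject_ids, self.labels) if l == "control"]
        canc = [s for s, l in zip(self.subject_ids, self.labels) if l == "cancer"]
        return self.subset(ctrl), self.subset(canc)
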