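"""Synthetic FTIR cohort generator.

Emulates the statistical structure of a two-arm blood-spectroscopy screening
study: ~30 subjects per class, two blood components (PBMC films and dried
plasma) measured five times each, broad Gaussian absorption bands at the
canonical biochemical positions, subject-level biological variation,
replicate-level instrument noise, slowly varying baseline/scattering drift,
and small class-dependent amplitude/shape effects planted at chosen
wavenumbers.  Because the planted effects are known exactly, every
downstream stage (QC, preprocessing, feature selection, classification,
cross-validation) can be validated by parameter recovery.

The generator makes no attempt at physical realism beyond band-level
phenomenology: no Mie scattering, film-thickness or instrument line-shape
model, and no acquisition interferogram.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .grid import WavenumberGrid, make_grid
from .spectra import COMPONENTS, Spectrum

# ---------------------------------------------------------------------------
# Band models
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BandModel:
    """Sum-of-Gaussians absorption model for one blood component.

    ``bands`` is a list of (center cm⁻¹, Gaussian sigma cm⁻¹, relative
    amplitude in absorbance units before subject-level rescaling).
    """

    bands: tuple[tuple[float, float, float], ...]
    component: str

    def __post_init__(self) -> None:
        if self.component not in COMPONENTS:
            raise ValueError(f"unknown component {self.component!r}")
        for center, width, amp in self.bands:
            if not (700.0 <= center <= 4000.0):
                raise ValueError(f"band center {center} outside [700, 4000]")
            if width <= 0:
                raise ValueError("band width must be positive")
            if amp < 0:
                raise ValueError("band amplitude must be non-negative")

    def centers(self) -> np.ndarray:
        return np.array([b[0] for b in self.bands])


# Relative amplitudes are loosely modelled on typical dried-film spectra:
# amide I dominates, PBMC films carry more nucleic-acid phosphate intensity
# (1240/1080), plasma more protein COO⁻/CH₃ (1400).
PBMC_BANDS = BandModel(
    bands=(
        (3290.0, 60.0, 0.55),   # amide A (N-H stretch)
        (2958.0, 12.0, 0.10),   # CH3 asym stretch
        (2925.0, 14.0, 0.12),   # CH2 asym stretch
        (2852.0, 10.0, 0.06),   # CH2 sym stretch
        (1655.0, 16.0, 1.00),   # amide I
        (1545.0, 14.0, 0.55),   # amide II
        (1452.0, 12.0, 0.18),   # CH2/CH3 bending
        (1400.0, 12.0, 0.18),   # COO- sym / CH3 bending
        (1240.0, 14.0, 0.14),   # PO2- asym stretch
        (1160.0, 9.0, 0.07),    # C-O stretch
        (1140.0, 8.0, 0.07),    # oligosaccharide C-OH
        (1080.0, 12.0, 0.16),   # PO2- sym stretch
        (1040.0, 12.0, 0.10),   # C-O carbohydrate
        (1012.0, 9.0, 0.05),    # C-O / glycogen
        (966.0, 8.0, 0.05),     # DNA backbone
        (920.0, 8.0, 0.03),     # ribose/nucleic acid
        (860.0, 8.0, 0.025),    # nucleic acid conformer
        (800.0, 8.0, 0.02),     # nucleic acid conformer
    ),
    component="PBMC",
)

PLASMA_BANDS = BandModel(
    bands=(
        (3290.0, 60.0, 0.60),
        (2958.0, 12.0, 0.09),
        (2928.0, 14.0, 0.10),
        (2872.0, 10.0, 0.05),
        (1655.0, 16.0, 1.00),
        (1545.0, 14.0, 0.60),
        (1452.0, 12.0, 0.20),
        (1400.0, 12.0, 0.25),
        (1310.0, 12.0, 0.08),   # amide III
        (1240.0, 14.0, 0.08),
        (1160.0, 9.0, 0.06),
        (1120.0, 10.0, 0.05),
        (1080.0, 12.0, 0.08),
        (1040.0, 12.0, 0.06),
        (920.0, 8.0, 0.02),
        (860.0, 8.0, 0.02),
        (800.0, 8.0, 0.015),
    ),
    component="plasma",
)

BAND_MODELS = {"PBMC": PBMC_BANDS, "plasma": PLASMA_BANDS}


# ---------------------------------------------------------------------------
# Effects and configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ClassEffect:
    """A small class-dependent perturbation of one absorption band.

    ``amplitude_delta`` and ``width_delta`` are fractional changes applied to
    the band nearest ``target_center``; ``applies_to`` names the diagnosis
    group carrying the effect.  ``component`` restricts the effect to one
    blood fraction (``None`` = both, where a matching band exists).
    """

    target_center: float
    amplitude_delta: float = 0.0
    width_delta: float = 0.0
    applies_to: str = "cancer"
    component: Optional[str] = None

    def __post_init__(self) -> None:
        if abs(self.amplitude_delta) >= 1:
            raise ValueError("|amplitude_delta| must be < 1")
        if self.width_delta <= -1:
            raise ValueError("width_delta must leave a positive width")
        if self.applies_to not in ("cancer", "benign"):
            raise ValueError("applies_to must be 'cancer' or 'benign'")
        if self.component is not None and self.component not in COMPONENTS:
            raise ValueError(f"unknown component {self.component!r}")


def default_class_effects() -> list[ClassEffect]:
    """Calibration defaults for the malignancy signature.

    Band choices follow the reported discriminative positions (PBMC
    ~1140/1545 and the 1180–1000 phosphate-carbohydrate region; plasma
    ~1160/1655); the magnitudes are the generator's own calibration choice —
    a few percent of band amplitude, i.e. 2–3× the subject-level biological
    scatter.
    """
    return [
        ClassEffect(1140.0, amplitude_delta=-0.05, component="PBMC"),
        ClassEffect(1545.0, width_delta=0.04, component="PBMC"),
        ClassEffect(1080.0, amplitude_delta=-0.03, component="PBMC"),
        ClassEffect(1160.0, amplitude_delta=0.05, component="plasma"),
        ClassEffect(1655.0, width_delta=-0.03, component="plasma"),
    ]


#: Clinical subgroup predicates usable as keys of ``CohortConfig.clinical_effects``.
CLINICAL_PREDICATES = {
    "mass_size": lambda r: r.mass_size_mm is not None and r.mass_size_mm > 20.0,
    "n_masses": lambda r: r.n_masses is not None and r.n_masses >= 2,
    "stage": lambda r: r.stage == "II",
    "histology": lambda r: r.histology == "ILC",
    "vascular_invasion": lambda r: bool(r.vascular_invasion),
    "node_involvement": lambda r: bool(r.node_involvement),
}


def default_clinical_effects() -> dict[str, ClassEffect]:
    return {
        "vascular_invasion": ClassEffect(1012.0, amplitude_delta=0.06, component="PBMC"),
    }


@dataclass
class SubjectRecord:
    """Per-subject clinical metadata; ``None`` encodes NA/not-reported."""

    subject_id: str
    group: str
    mass_size_mm: Optional[float] = None
    n_masses: Optional[int] = None
    stage: Optional[str] = None
    histology: Optional[str] = None
    vascular_invasion: Optional[bool] = None
    node_involvement: Optional[bool] = None
    receptors: frozenset = frozenset()
    hemolyzed_plasma: bool = False

    def __post_init__(self) -> None:
        if self.group not in ("cancer", "benign", "healthy"):
            raise ValueError(f"unknown group {self.group!r}")
        if self.mass_size_mm is not None and self.mass_size_mm <= 0:
            raise ValueError("mass_size_mm must be positive when present")
        self.receptors = frozenset(self.receptors)


@dataclass
class CohortConfig:
    """Study-design parameters of a simulated cohort.

    Defaults mirror the reference study design: 29 cancer subjects, 30
    controls (15 benign + 15 healthy), 5 replicate measurements per subject
    and component.  Noise scales are fractional (subject-level band
    amplitude scatter) and absolute absorbance units (replicate noise,
    representative of a well-averaged FTIR measurement).
    """

    n_cancer: int = 29
    n_benign: int = 15
    n_healthy: int = 15
    replicates_per_subject: int = 5
    subject_sd: float = 0.02
    replicate_sd: float = 2e-4
    #: (slope, offset, broad-scatter amplitude) of the additive baseline.
    baseline: tuple[float, float, float] = (0.01, 0.02, 0.015)
    effects: list[ClassEffect] = field(default_factory=default_class_effects)
    clinical_effects: dict[str, ClassEffect] = field(default_factory=default_clinical_effects)
    hemolysis_rate: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_cancer, self.n_benign, self.n_healthy) < 0:
            raise ValueError("subject counts must be non-negative")
        if self.replicates_per_subject < 1:
            raise ValueError("replicates_per_subject must be >= 1")
        if self.subject_sd < 0 or self.replicate_sd < 0:
            raise ValueError("noise scales must be non-negative")
        if not 0 <= self.hemolysis_rate < 1:
            raise ValueError("hemolysis_rate must be in [0, 1)")
        for key in self.clinical_effects:
            if key not in CLINICAL_PREDICATES:
                raise ValueError(f"unknown clinical parameter {key!r}")


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

_AMIDE_I_WINDOW = (1600.0, 1700.0)

# Reference noise scales the default configuration uses.  The amide-I target
# jitter (subject level) and baseline jitter (replicate level) shrink
# proportionally below these references, so a zero-noise configuration is
# fully deterministic: pure band sum + fixed baseline.
_REF_SUBJECT_SD = 0.02
_REF_REPLICATE_SD = 2e-4


def _gaussians(grid: WavenumberGrid, centers, widths, amps) -> np.ndarray:
    x = grid.values[None, :]
    c = np.asarray(centers)[:, None]
    w = np.asarray(widths)[:, None]
    a = np.asarray(amps)[:, None]
    return (a * np.exp(-0.5 * ((x - c) / w) ** 2)).sum(axis=0)


def _nearest_band(model: BandModel, center: float) -> int:
    i = int(np.argmin(np.abs(model.centers() - center)))
    if abs(model.bands[i][0] - center) > 30.0:
        raise ValueError(
            f"no {model.component} band within 30 cm^-1 of effect target {center}"
        )
    return i


def _effective_bands(
    config: CohortConfig, record: SubjectRecord, model: BandModel
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Band centers/widths/amplitudes after class and clinical effects."""
    centers = np.array([b[0] for b in model.bands])
    widths = np.array([b[1] for b in model.bands])
    amps = np.array([b[2] for b in model.bands])
    active = [e for e in config.effects if e.applies_to == record.group]
    for key, eff in config.clinical_effects.items():
        if record.group == "cancer" and CLINICAL_PREDICATES[key](record):
            active.append(eff)
    for eff in active:
        if eff.component is not None and eff.component != model.component:
            continue
        i = _nearest_band(model, eff.target_center)
        amps[i] *= 1.0 + eff.amplitude_delta
        widths[i] *= 1.0 + eff.width_delta
    return centers, widths, amps


def simulate_subject(
    config: CohortConfig,
    record: SubjectRecord,
    component: str,
    stream: np.random.Generator,
    grid: WavenumberGrid | None = None,
) -> list[Spectrum]:
    """Simulate all replicate spectra of one subject for one blood component.

    The subject's noiseless base spectrum is the band sum with per-band
    multiplicative biological scatter (sigma ``subject_sd``) and any matching
    class/clinical effects, rescaled so the amide I maximum falls in
    [0.55, 0.90] absorbance (inside the QC acceptance window).  Each
    replicate then adds its own baseline realisation and white noise.
    """
    if component not in COMPONENTS:
        raise ValueError(f"unknown component {component!r}")
    if grid is None:
        grid = make_grid("full")
    model = BAND_MODELS[component]
    centers, widths, amps = _effective_bands(config, record, model)

    subject_factors = 1.0 + config.subject_sd * stream.standard_normal(len(amps))
    base = _gaussians(grid, centers, widths, amps * subject_factors)

    lo, hi = _AMIDE_I_WINDOW
    window = (grid.values >= lo) & (grid.values <= hi)
    subject_jitter = min(1.0, config.subject_sd / _REF_SUBJECT_SD)
    target = 0.725 + 0.175 * (2.0 * stream.uniform() - 1.0) * subject_jitter
    base *= target / base[window].max()

    slope, offset, scatter = config.baseline
    x01 = (grid.values - grid.values[0]) / (grid.values[-1] - grid.values[0])
    broad = np.exp(-0.5 * ((grid.values - 2500.0) / 900.0) ** 2)

    replicate_jitter = min(1.0, config.replicate_sd / _REF_REPLICATE_SD)
    spectra = []
    for rep in range(1, config.replicates_per_subject + 1):
        u = 1.0 + (stream.uniform(size=3) - 0.5) * replicate_jitter
        baseline = offset * u[0] + slope * u[1] * x01 + scatter * u[2] * broad
        noise = config.replicate_sd * stream.standard_normal(len(grid))
        spectra.append(
            Spectrum(
                grid=grid,
                absorbance=base + baseline + noise,
                subject_id=record.subject_id,
                component=component,
                replicate=rep,
            )
        )
    return spectra


# Table-1-style marginal frequencies used to draw cancer clinical covariates.
_HISTOLOGY = (("IDC", 22), ("ILC", 4), ("other", 3))
_STAGE = (("I", 1), ("II", 14), ("III", 4), (None, 10))
_SIZE_BINS = (((5.0, 10.0), 8), ((10.0, 20.0), 8), ((20.0, 45.0), 11), (None, 2))
_P_ER, _P_PR, _P_HER2 = 25 / 29, 22 / 29, 2 / 29
_P_MULTI_MASS = 0.3
_P_VASCULAR = 0.35
_P_NODE = 0.40


def _choice(rng: np.random.Generator, table):
    labels = [t[0] for t in table]
    weights = np.array([t[1] for t in table], dtype=float)
    return labels[rng.choice(len(labels), p=weights / weights.sum())]


def _draw_record(
    rng: np.random.Generator, subject_id: str, group: str, hemolysis_rate: float
) -> SubjectRecord:
    hemolyzed = bool(rng.uniform() < hemolysis_rate)
    if group != "cancer":
        return SubjectRecord(subject_id=subject_id, group=group, hemolyzed_plasma=hemolyzed)
    histology = _choice(rng, _HISTOLOGY)
    stage = _choice(rng, _STAGE)
    size_bin = _choice(rng, _SIZE_BINS)
    size = None if size_bin is None else float(rng.uniform(*size_bin))
    n_masses = 1 if rng.uniform() > _P_MULTI_MASS else int(rng.integers(2, 4))
    receptors = set()
    if rng.uniform() < _P_ER:
        receptors.add("ER")
    if rng.uniform() < _P_PR:
        receptors.add("PR")
    if rng.uniform() < _P_HER2:
        receptors.add("Her2")
    return SubjectRecord(
        subject_id=subject_id,
        group=group,
        mass_size_mm=size,
        n_masses=n_masses,
        stage=stage,
        histology=histology,
        vascular_invasion=bool(rng.uniform() < _P_VASCULAR),
        node_involvement=bool(rng.uniform() < _P_NODE),
        receptors=frozenset(receptors),
        hemolyzed_plasma=hemolyzed,
    )


def simulate_cohort(config: CohortConfig) -> tuple[list[Spectrum], list[SubjectRecord]]:
    """Simulate a full cohort: spectra for every subject × component × replicate.

    A master seed spawns one independent random substream per subject, so a
    given subject's spectra are reproducible regardless of cohort size.
    Plasma spectra of hemolysis-flagged subjects are not emitted (the sample
    is unusable), which is how the generator reproduces component-missing
    subjects.
    """
    grid = make_grid("full")
    groups = (
        [("C", "cancer")] * config.n_cancer
        + [("B", "benign")] * config.n_benign
        + [("H", "healthy")] * config.n_healthy
    )
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(len(groups))
    spectra: list[Spectrum] = []
    records: list[SubjectRecord] = []
    counters = {"C": 0, "B": 0, "H": 0}
    for (prefix, group), child in zip(groups, children):
        counters[prefix] += 1
        subject_id = f"{prefix}{counters[prefix]:03d}"
        meta_ss, pbmc_ss, plasma_ss = child.spawn(3)
        record = _draw_record(
            np.random.default_rng(meta_ss), subject_id, group, config.hemolysis_rate
        )
        records.append(record)
        spectra.extend(
            simulate_subject(config, record, "PBMC", np.random.default_rng(pbmc_ss), grid)
        )
        if not record.hemolyzed_plasma:
            spectra.extend(
                simulate_subject(
                    config, record, "plasma", np.random.default_rng(plasma_ss), grid
                )
            )
    return spectra, records


# ---------------------------------------------------------------------------
# Measurement artifacts
# ---------------------------------------------------------------------------

# Approximate rotational-vibrational water-vapor line positions (cm⁻¹) in the
# amide window; narrow relative to any biological band.
_VAPOR_LINES = (
    1419.0, 1436.0, 1448.0, 1457.0, 1465.0, 1473.0, 1489.0, 1507.0, 1522.0,
    1540.0, 1559.0, 1576.0, 1587.0, 1616.0, 1636.0, 1653.0, 1662.0, 1670.0,
    1684.0, 1700.0, 1717.0, 1734.0, 1751.0, 1772.0, 1790.0,
)


def inject_artifact(spectrum: Spectrum, kind: str) -> Spectrum:
    """Apply a QC-relevant measurement artifact to a spectrum.

    ``overexposed``/``underexposed`` scale the spectrum outside the 0.5–1.0
    amide I acceptance window; ``water_vapor`` superimposes narrow
    (sigma 1.5 cm⁻¹) atmospheric lines in 1400–1800 cm⁻¹; ``none`` is the
    identity.
    """
    if kind == "none":
        return spectrum.with_values(spectrum.absorbance.copy())
    lo, hi = _AMIDE_I_WINDOW
    window = (spectrum.grid.values >= lo) & (spectrum.grid.values <= hi)
    amide_max = spectrum.absorbance[window].max()
    if kind == "overexposed":
        return spectrum.with_values(spectrum.absorbance * (1.25 / amide_max))
    if kind == "underexposed":
        return spectrum.with_values(spectrum.absorbance * (0.35 / amide_max))
    if kind == "water_vapor":
        x = spectrum.grid.values
        lines = np.zeros_like(x)
        for i, center in enumerate(_VAPOR_LINES):
            sign = 1.0 if i % 2 == 0 else -1.0
            lines += sign * 0.015 * np.exp(-0.5 * ((x - center) / 1.5) ** 2)
        return spectrum.with_values(spectrum.absorbance + lines)
    raise ValueError(f"unknown artifact kind {kind!r}")
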