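"""Canonical wavenumber axes for mid-infrared absorption spectra.

The instrument axis spans 700–4000 cm⁻¹ with 6845 points; chemometric
analysis is restricted to the biochemical fingerprint region (≤ 1800 cm⁻¹),
which on this axis contains exactly 2282 points.  The grid is defined by its
endpoint values and point count; the spacing (3300/6844 ≈ 0.48218 cm⁻¹,
printing as 0.482) is derived from them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

FULL_MIN = 700.0
FULL_MAX = 4000.0
FULL_POINTS = 6845
FINGERPRINT_MAX = 1800.0
FINGERPRINT_POINTS = 2282

#: Uniformity tolerance on the spacing, in cm⁻¹.
_SPACING_TOL = 1e-9


@dataclass(frozen=True, eq=False)
class WavenumberGrid:
    """A strictly increasing, uniformly spaced wavenumber axis (cm⁻¹)."""

    values: np.ndarray
    region: str = "custom"

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 1 or values.size < 2:
            raise ValueError("grid needs at least two wavenumber values")
        steps = np.diff(values)
        if np.any(steps <= 0):
            raise ValueError("wavenumbers must be strictly increasing")
        if np.ptp(steps) > _SPACING_TOL:
            raise ValueError(
                f"grid spacing non-uniform beyond {_SPACING_TOL} cm^-1 "
                f"(spread {np.ptp(steps):.3g})"
            )
        if self.region == "full" and values.size != FULL_POINTS:
            raise ValueError(f"full grid must have {FULL_POINTS} points")
        if self.region == "fingerprint" and values.size != FINGERPRINT_POINTS:
            raise ValueError(f"fingerprint grid must have {FINGERPRINT_POINTS} points")

    @property
    def spacing(self) -> float:
        return (self.values[-1] - self.values[0]) / (self.values.size - 1)

    def __len__(self) -> int:
        return self.values.size

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, WavenumberGrid):
            return NotImplemented
        return self.region == other.region and np.array_equal(self.values, other.values)

    def __hash__(self) -> int:  # frozen dataclass; identity-level hash is enough
        return hash((self.region, self.values.size, self.values[0], self.values[-1]))


def make_grid(region: str = "full") -> WavenumberGrid:
    """Build the canonical measurement axis.

    Parameters
    ----------
    region:
        ``"full"`` — 6845 points spanning 700–4000 cm⁻¹ inclusive;
        ``"fingerprint"`` — the 2282 full-grid points with wavenumber ≤ 1800.
    """
    if region not in ("full", "fingerprint"):
        raise ValueError(f"unknown grid region {region!r}")
    full = np.linspace(FULL_MIN, FULL_MAX, FULL_POINTS)
    if region == "full":
        return WavenumberGrid(full, "full")
    return WavenumberGrid(full[full <= FINGERPRINT_MAX], "fingerprint")
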