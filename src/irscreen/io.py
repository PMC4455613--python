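"""Reading and writing spectra and clinical metadata.

Supported on-disk formats are deliberately open and text-based:

* JCAMP-DX, restricted to the unambiguous ``##XYDATA=(X++(Y..Y))`` table
  with AFFN numerics (no ASDF/DIFDUP compression);
* a wide CSV matrix (first column wavenumber, one column per measurement,
  header cells ``subject|component|replicate``);
* a flat metadata CSV with one row per subject, NA/NR tokens allowed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
import pandas as pd

from .grid import (
    FINGERPRINT_POINTS,
    FULL_POINTS,
    WavenumberGrid,
    make_grid,
)
from .spectra import Spectrum
from .synth import SubjectRecord

log = logging.getLogger(__name__)

_GRID_ATOL = 1e-6


def _canonical_grid(values: np.ndarray) -> WavenumberGrid:
    """Recognize the canonical axes so round-trips restore the named region."""
    for region, npts in (("full", FULL_POINTS), ("fingerprint", FINGERPRINT_POINTS)):
        if values.size == npts:
            canonical = make_grid(region)
            if np.allclose(values, canonical.values, atol=_GRID_ATOL):
                return canonical
    return WavenumberGrid(values, "custom")


# ---------------------------------------------------------------------------
# JCAMP-DX
# ---------------------------------------------------------------------------


class JcampError(ValueError):
    """Malformed or unsupported JCAMP-DX content."""


def write_jcampdx(spectrum: Spectrum, path: str | Path) -> None:
    """Write a spectrum as a JCAMP-DX ``(X++(Y..Y))`` AFFN table.

    Absorbance is stored as scaled integers via ##YFACTOR so the round trip
    through :func:`read_jcampdx` is exact to better than 1e-9 absorbance.
    """
    if len(spectrum.grid) < 2:
        raise JcampError("refusing to write a spectrum with fewer than 2 points")
    x = spectrum.grid.values
    y = spectrum.absorbance
    ymax = max(np.abs(y).max(), 1e-12)
    yfactor = ymax / 1e9  # integer range ±1e9 → abs error ≤ yfactor/2 < 1e-9
    yints = np.rint(y / yfactor).astype(np.int64)
    lines = [
        "##TITLE=irscreen simulated spectrum",
        "##JCAMP-DX=4.24",
        "##DATA TYPE=INFRARED SPECTRUM",
        "##XUNITS=1/CM",
        "##YUNITS=ABSORBANCE",
        f"##$SUBJECTID={spectrum.subject_id}",
        f"##$COMPONENT={spectrum.component}",
        f"##$REPLICATE={spectrum.replicate}",
        f"##NPOINTS={len(x)}",
        f"##FIRSTX={x[0]:.10g}",
        f"##LASTX={x[-1]:.10g}",
        "##XFACTOR=1.0",
        f"##YFACTOR={yfactor:.17g}",
        f"##FIRSTY={y[0]:.10g}",
        "##XYDATA=(X++(Y..Y))",
    ]
    per_line = 6
    for start in range(0, len(x), per_line):
        chunk = yints[start : start + per_line]
        lines.append(f"{x[start]:.6f} " + " ".join(str(v) for v in chunk))
    lines.append("##END=")
    Path(path).write_text("\n".join(lines) + "\n")


def read_jcampdx(path: str | Path) -> Spectrum:
    """Read a spectrum written in the supported JCAMP-DX subset.

    The wavenumber axis is reconstructed from FIRSTX/LASTX/NPOINTS; Y values
    are de-scaled by YFACTOR.  The returned axis is ascending regardless of
    file order.
    """
    records: dict[str, str] = {}
    ydata: list[float] = []
    in_table = False
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith("##"):
            label, _, value = line[2:].partition("=")
            label = label.replace(" ", "").upper()
            records[label] = value.strip()
            in_table = label == "XYDATA"
            if in_table and records[label] != "(X++(Y..Y))":
                raise JcampError(f"unsupported XYDATA form {records[label]!r}")
            continue
        if in_table:
            fields = line.split()
            ydata.extend(float(v) for v in fields[1:])  # first field is X
    for required in ("NPOINTS", "FIRSTX", "LASTX", "XYDATA"):
        if required not in records:
            raise JcampError(f"missing required record ##{required}=")
    npoints = int(records["NPOINTS"])
    if npoints != len(ydata):
        raise JcampError(
            f"##NPOINTS={npoints} disagrees with {len(ydata)} Y values in the table"
        )
    firstx, lastx = float(records["FIRSTX"]), float(records["LASTX"])
    yfactor = float(records.get("YFACTOR", "1"))
    x = np.linspace(firstx, lastx, npoints)
    y = np.asarray(ydata) * yfactor
    if firstx > lastx:  # descending file order → flip both axes
        x, y = x[::-1], y[::-1]
    return Spectrum(
        grid=_canonical_grid(x),
        absorbance=y,
        subject_id=records.get("$SUBJECTID", "unknown"),
        component=records.get("$COMPONENT", "PBMC"),
        replicate=int(records.get("$REPLICATE", "1")),
    )


# ---------------------------------------------------------------------------
# Wide CSV matrix
# ---------------------------------------------------------------------------


def _measurement_key(spectrum: Spectrum) -> str:
    return f"{spectrum.subject_id}|{spectrum.component}|{spectrum.replicate}"


def write_csv_matrix(spectra: list[Spectrum], path: str | Path) -> None:
    """Write spectra as a wide CSV (wavenumber column + one column each)."""
    if not spectra:
        raise ValueError("no spectra to write")
    grid = spectra[0].grid
    for s in spectra[1:]:
        if s.grid != grid:
            raise ValueError("all spectra must share one grid")
    keys = [_measurement_key(s) for s in spectra]
    if len(set(keys)) != len(keys):
        raise ValueError("duplicate measurement ids")
    frame = pd.DataFrame(
        {key: s.absorbance for key, s in zip(keys, spectra)},
        index=pd.Index(grid.values, name="wavenumber"),
    )
    frame.to_csv(path, float_format="%.12g")


def read_csv_matrix(path: str | Path) -> list[Spectrum]:
    """Read a wide CSV spectra matrix into one Spectrum per column."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(",")
    if len(set(header)) != len(header):
        raise ValueError("duplicate measurement ids in header")
    frame = pd.read_csv(path)
    if frame.shape[1] < 2:
        raise ValueError("matrix needs a wavenumber column plus >= 1 measurement")
    frame = frame.sort_values(frame.columns[0]).reset_index(drop=True)
    values = frame.iloc[:, 0].to_numpy(dtype=float)
    if np.unique(values).size != values.size:
        raise ValueError("wavenumber column contains duplicates")
    grid = _canonical_grid(values)  # raises on non-uniform spacing
    keys = list(frame.columns[1:])
    if len(set(keys)) != len(keys):
        raise ValueError("duplicate measurement ids in header")
    spectra = []
    for key in keys:
        try:
            subject_id, component, replicate = key.split("|")
        except ValueError as exc:
            raise ValueError(
                f"header {key!r} must look like subject|component|replicate"
            ) from exc
        spectra.append(
            Spectrum(
                grid=grid,
                absorbance=frame[key].to_numpy(dtype=float),
                subject_id=subject_id,
                component=component,
                replicate=int(replicate),
            )
        )
    return spectra


# ---------------------------------------------------------------------------
# Metadata
# ---------------------------------------------------------------------------

_NA_TOKENS = {"", "NA", "NR", "NA/NR", "nan", "None"}

_META_COLUMNS = [
    "subject_id",
    "group",
    "mass_size_mm",
    "n_masses",
    "stage",
    "histology",
    "vascular_invasion",
    "node_involvement",
    "receptors",
    "hemolyzed_plasma",
]


def _parse_optional(token, cast):
    if token is None or (isinstance(token, float) and np.isnan(token)):
        return None
    token = str(token).strip()
    if token in _NA_TOKENS:
        return None
    return cast(token)


def _parse_bool(token: str) -> bool:
    if token.lower() in ("true", "1", "yes"):
        return True
    if token.lower() in ("false", "0", "no"):
        return False
    raise ValueError(f"cannot interpret boolean token {token!r}")


def write_metadata(records: list[SubjectRecord], path: str | Path) -> None:
    rows = []
    for r in records:
        rows.append(
            {
                "subject_id": r.subject_id,
                "group": r.group,
                "mass_size_mm": "" if r.mass_size_mm is None else repr(r.mass_size_mm),
                "n_masses": "" if r.n_masses is None else r.n_masses,
                "stage": "NA/NR" if r.stage is None else r.stage,
                "histology": "NA/NR" if r.histology is None else r.histology,
                "vascular_invasion": "" if r.vascular_invasion is None else r.vascular_invasion,
                "node_involvement": "" if r.node_involvement is None else r.node_involvement,
                "receptors": ";".join(sorted(r.receptors)),
                "hemolyzed_plasma": r.hemolyzed_plasma,
            }
        )
    pd.DataFrame(rows, columns=_META_COLUMNS).to_csv(path, index=False)


def read_metadata(path: str | Path) -> list[SubjectRecord]:
    """Read the subject metadata CSV; NA/NR tokens map to missing values."""
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    if frame.empty:
        log.warning("metadata file %s contains no subjects", path)
        return []
    records = []
    for i, row in frame.iterrows():
        group = row.get("group", "").strip()
        if group not in ("cancer", "benign", "healthy"):
            raise ValueError(f"row {i}: unknown group label {group!r}")
        size = _parse_optional(row.get("mass_size_mm"), float)
        if size is not None and size <= 0:
            raise ValueError(f"row {i}: non-positive mass size {size}")
        receptors = row.get("receptors", "").strip()
        records.append(
            SubjectRecord(
                subject_id=row["subject_id"].strip(),
                group=group,
                mass_size_mm=size,
                n_masses=_parse_optional(row.get("n_masses"), int),
                stage=_parse_optional(row.get("stage"), str),
                histology=_parse_optional(row.get("histology"), str),
                vascular_invasion=_parse_optional(row.get("vascular_invasion"), _parse_bool),
                node_involvement=_parse_optional(row.get("node_involvement"), _parse_bool),
                receptors=frozenset(receptors.split(";")) if receptors else frozenset(),
                hemolyzed_plasma=bool(
                    _parse_optional(row.get("hemolyzed_plasma"), _parse_bool) or False
                ),
            )
        )
    return records


# ---------------------------------------------------------------------------
# Cohort summary
# ---------------------------------------------------------------------------


def _pct(count: int, denom: int) -> float:
    """Percentage rounded half-up to one decimal, as printed in cohort tables."""
    if denom == 0:
        return 0.0
    return float(
        (Decimal(100 * count) / Decimal(denom)).quantize(Decimal("0.1"), ROUND_HALF_UP)
    )


@dataclass
class CohortSummary:
    """Counts and one-decimal percentages per clinical field.

    ``tables`` maps field name → list of (category, count, percent); the
    clinical fields use the cancer-group size as denominator.
    """

    n_cancer: int
    n_control: int
    tables: dict[str, list[tuple[str, int, float]]]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"field": field, "category": cat, "count": n, "percent": pct}
            for field, entries in self.tables.items()
            for cat, n, pct in entries
        ]
        return pd.DataFrame(rows)


def _size_bin(size_mm: float | None) -> str:
    if size_mm is None:
        return "NA/NR"
    if size_mm <= 10:
        return "<=10"
    if size_mm <= 20:
        return "10<=20"
    return "20<"


def summarize_cohort(records: list[SubjectRecord]) -> CohortSummary:
    """Tabulate the cohort the way clinical characteristics tables print it."""
    if not records:
        raise ValueError("cannot summarize an empty cohort")
    cancer = [r for r in records if r.group == "cancer"]
    n_cancer = len(cancer)
    n_control = len(records) - n_cancer
    n_total = len(records)

    tables: dict[str, list[tuple[str, int, float]]] = {}
    tables["group"] = [
        (g, n, _pct(n, n_total))
        for g, n in (
            ("cancer", n_cancer),
            ("benign", sum(r.group == "benign" for r in records)),
            ("healthy", sum(r.group == "healthy" for r in records)),
        )
    ]

    def tabulate(field: str, value_of) -> None:
        counts: dict[str, int] = {}
        for r in cancer:
            key = value_of(r)
            counts[key] = counts.get(key, 0) + 1
        tables[field] = [(k, n, _pct(n, n_cancer)) for k, n in sorted(counts.items())]

    tabulate("histology", lambda r: r.histology or "NA/NR")
    tabulate("stage", lambda r: r.stage or "NA/NR")
    tabulate("size", lambda r: _size_bin(r.mass_size_mm))
    tables["receptors"] = [
        (name, n, _pct(n, n_cancer))
        for name, n in (
            ("ER+", sum("ER" in r.receptors for r in cancer)),
            ("PR+", sum("PR" in r.receptors for r in cancer)),
            ("Her2+", sum("Her2" in r.receptors for r in cancer)),
        )
    ]
    return CohortSummary(n_cancer=n_cancer, n_control=n_control, tables=tables)
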