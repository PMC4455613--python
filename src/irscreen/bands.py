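"""Static biochemical assignment table for fingerprint-region bands.

Informational only: annotations label selected wavenumbers in reports and
never feed back into selection or classification.
"""

from __future__ import annotations

from dataclasses import dataclass

#: (low cm⁻¹, high cm⁻¹, assignment).  Intervals are the conventional
#: vibrational assignments for dried biofluid films.
ASSIGNMENT_TABLE: tuple[tuple[float, float, str], ...] = (
    (1600.0, 1700.0, "amide I (protein secondary structure)"),
    (1520.0, 1570.0, "amide II (N-H bend / C-N stretch)"),
    (1440.0, 1465.0, "CH2/CH3 bending (lipids, proteins)"),
    (1380.0, 1420.0, "COO- symmetric stretch / CH3 bending"),
    (1290.0, 1330.0, "amide III"),
    (1220.0, 1260.0, "PO2- asymmetric stretch (nucleic acids, phospholipids)"),
    (1150.0, 1175.0, "C-O stretch (proteins, carbohydrates)"),
    (1125.0, 1150.0, "oligosaccharide C-OH stretch"),
    (1065.0, 1095.0, "PO2- symmetric stretch"),
    (1020.0, 1060.0, "C-O carbohydrate / glycogen"),
    (1000.0, 1020.0, "C-O, C-C symmetric vibrations"),
    (955.0, 975.0, "DNA backbone C-C/C-O"),
    (910.0, 930.0, "ribose / nucleic acid vibration"),
    (850.0, 880.0, "nucleic acid conformer (C3'-endo/anti)"),
    (790.0, 815.0, "nucleic acid conformer"),
)

#: A wavenumber farther than this from every table interval is "unassigned".
MAX_ASSIGN_DISTANCE = 30.0


@dataclass(frozen=True)
class BandAnnotation:
    wavenumber: float
    assignment: str
    distance: float  # cm⁻¹ to the matched interval (0 if inside it)


def annotate_bands(wavenumbers) -> list[BandAnnotation]:
    """Map wavenumbers to the nearest assignment-table entry.

    The reported distance is 0 for a wavenumber inside the matched interval,
    otherwise the gap to its nearest edge; beyond 30 cm⁻¹ from every entry
    the annotation is ``"unassigned"``.
    """
    annotations = []
    for wn in wavenumbers:
        wn = float(wn)
        if not 700.0 <= wn <= 1800.0:
            raise ValueError(f"wavenumber {wn} outside the fingerprint region")
        best_label, best_dist = "unassigned", float("inf")
        for lo, hi, label in ASSIGNMENT_TABLE:
            dist = 0.0 if lo <= wn <= hi else min(abs(wn - lo), abs(wn - hi))
            if dist < best_dist:
                best_label, best_dist = label, dist
        if best_dist > MAX_ASSIGN_DISTANCE:
            best_label, best_dist = "unassigned", best_dist
        annotations.append(BandAnnotation(wn, best_label, best_dist))
    return annotations
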