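"""Marker-overlay co-labeling and calyx-proximity classification.

Co-labeling is determined by overlaying two independently marked point
sets (e.g. Olig2 and SOX10 soma centers) and pairing marks that coincide
within a tolerance.  Matching is greedy mutual nearest neighbor: the
globally closest unmatched pair within tolerance is paired first, then
the next, until no pair remains — deterministic, order-independent and
auditable.  Default tolerances: 5 um for somata (about a soma radius),
1 um for axon cross-profiles.

Calyx proximity follows the sampling-circle procedure: a circle is drawn
around the VGluT1-positive calyx, its diameter is summed with the mean
S100 soma diameter (17 um), and every cell whose soma disc lies fully
within the resulting concentric sampling circle is counted and
partitioned by its labeling (S100 only / Olig2 only / double).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial.distance import cdist

from glioquant.geometry_io import CellMark

logger = logging.getLogger("glioquant")

DEFAULT_SOMA_TOLERANCE_UM = 5.0
DEFAULT_AXON_TOLERANCE_UM = 1.0
DEFAULT_SOMA_DIAMETER_UM = 17.0  # mean S100-positive soma (n = 68, P10)


@dataclass(frozen=True)
class MatchResult:
    """Outcome of overlaying two mark sets."""

    n_only_a: int
    n_only_b: int
    n_double: int
    pairs: tuple[tuple[int, int], ...]
    tolerance_um: float

    @property
    def n_a(self) -> int:
        return self.n_only_a + self.n_double

    @property
    def n_b(self) -> int:
        return self.n_only_b + self.n_double

    @property
    def total_cells(self) -> int:
        """Distinct somata: singles plus each matched pair counted once."""
        return self.n_only_a + self.n_only_b + self.n_double


def _coords(marks: Sequence[CellMark] | np.ndarray) -> np.ndarray:
    if isinstance(marks, np.ndarray):
        return np.asarray(marks, dtype=float).reshape(-1, 2)
    return np.array([(m.x_px, m.y_px) for m in marks], dtype=float).reshape(-1, 2)


def match_marks(
    a: Sequence[CellMark] | np.ndarray,
    b: Sequence[CellMark] | np.ndarray,
    tolerance_um: float = DEFAULT_SOMA_TOLERANCE_UM,
) -> MatchResult:
    """Greedy mutual-nearest-neighbor overlay of two mark sets.

    Coordinates must already be in um (or share a frame whose unit the
    tolerance is expressed in).  Ties in distance are broken by index so
    the result is deterministic.
    """
    if tolerance_um <= 0:
        raise ValueError("tolerance must be > 0")
    pa, pb = _coords(a), _coords(b)
    na, nb = len(pa), len(pb)
    if na == 0 or nb == 0:
        return MatchResult(na, nb, 0, (), tolerance_um)
    d = cdist(pa, pb)
    ia, ib = np.nonzero(d <= tolerance_um)
    cand = sorted(zip(d[ia, ib], ia.tolist(), ib.tolist()))
    used_a: set[int] = set()
    used_b: set[int] = set()
    pairs: list[tuple[int, int]] = []
    for _, i, j in cand:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        pairs.append((i, j))
    nd = len(pairs)
    return MatchResult(na - nd, nb - nd, nd, tuple(pairs), tolerance_um)


def fraction_table(counts: Mapping[str, int]) -> dict[str, float]:
    """Percentages of co-labeling categories (summing to 100).

    ``counts`` maps category names (e.g. ``only_A``, ``only_B``,
    ``double``, or the seven triple-marker categories) to cell counts.
    """
    total = sum(counts.values())
    if total <= 0:
        raise ValueError("fraction table needs a positive total count")
    if any(v < 0 for v in counts.values()):
        raise ValueError("counts must be >= 0")
    return {k: 100.0 * v / total for k, v in counts.items()}


def match_fractions(result: MatchResult, label_a: str = "A", label_b: str = "B") -> dict[str, float]:
    """Percentage of only-A / only-B / double cells from a MatchResult."""
    return fraction_table(
        {
            f"only_{label_a}": result.n_only_a,
            f"only_{label_b}": result.n_only_b,
            "double": result.n_double,
        }
    )


def match_marks_triple(
    a: Sequence[CellMark] | np.ndarray,
    b: Sequence[CellMark] | np.ndarray,
    c: Sequence[CellMark] | np.ndarray,
    tolerance_um: float = DEFAULT_SOMA_TOLERANCE_UM,
) -> dict[str, int]:
    """Three-marker overlay (e.g. S100 / Olig2 / SOX10).

    A and B are matched first; AB pairs (midpoints) and the remaining
    singles are then matched against C.  Returns counts of the seven
    categories ``only_A ... A+B+C``.
    """
    pa, pb, pc = _coords(a), _coords(b), _coords(c)
    ab = match_marks(pa, pb, tolerance_um)
    ab_centers = (
        np.array([(pa[i] + pb[j]) / 2.0 for i, j in ab.pairs]).reshape(-1, 2)
    )
    a_single = np.delete(pa, [i for i, _ in ab.pairs], axis=0)
    b_single = np.delete(pb, [j for _, j in ab.pairs], axis=0)

    counts = dict.fromkeys(
        ["only_A", "only_B", "only_C", "A+B", "A+C", "B+C", "A+B+C"], 0
    )
    abc = match_marks(ab_centers, pc, tolerance_um)
    counts["A+B+C"] = abc.n_double
    counts["A+B"] = abc.n_only_a
    pc_left = np.delete(pc, [j for _, j in abc.pairs], axis=0)
    ac = match_marks(a_single, pc_left, tolerance_um)
    counts["A+C"] = ac.n_double
    counts["only_A"] = ac.n_only_a
    pc_left2 = np.delete(pc_left, [j for _, j in ac.pairs], axis=0)
    bc = match_marks(b_single, pc_left2, tolerance_um)
    counts["B+C"] = bc.n_double
    counts["only_B"] = bc.n_only_a
    counts["only_C"] = bc.n_only_b
    return counts


# ---------------------------------------------------------------------------
# calyx proximity


@dataclass(frozen=True)
class CalyxScene:
    """One calyx of Held with the somata marked around it (coordinates um)."""

    calyx_center: tuple[float, float]
    calyx_diameter_um: float
    cells: tuple[CellMark, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.calyx_diameter_um <= 0:
            raise ValueError("calyx diameter must be > 0")
        object.__setattr__(self, "cells", tuple(self.cells))


def sampling_circle(
    calyx_diameter_um: float, cell_diameter_um: float = DEFAULT_SOMA_DIAMETER_UM
) -> float:
    """Diameter of the calyx-proximity sampling circle: the calyx-circle
    diameter plus the mean soma diameter, concentric with the calyx."""
    if calyx_diameter_um <= 0 or cell_diameter_um <= 0:
        raise ValueError("diameters must be > 0")
    return calyx_diameter_um + cell_diameter_um


def classify_proximal(
    scene: CalyxScene,
    markers: tuple[str, str] = ("S100", "Olig2"),
    cell_diameter_um: float = DEFAULT_SOMA_DIAMETER_UM,
) -> dict[str, int]:
    """Count cells whose soma lies fully inside the sampling circle,
    partitioned by labeling.

    A cell counts iff ``dist(center, calyx_center) + soma_radius <=
    sampling_radius`` (the soma approximated as a disc of its measured
    diameter; the configured default is used, and logged, when no
    diameter was measured).  Returns counts for ``only_<m1>``,
    ``only_<m2>``, ``double`` and ``total``.
    """
    m1, m2 = markers
    r_samp = sampling_circle(scene.calyx_diameter_um, cell_diameter_um) / 2.0
    cx, cy = scene.calyx_center
    counts = {f"only_{m1}": 0, f"only_{m2}": 0, "double": 0}
    for cell in scene.cells:
        dia = cell.soma_diameter_um
        if dia is None:
            logger.info("cell without soma diameter: using default %.1f um", cell_diameter_um)
            dia = cell_diameter_um
        dist = float(np.hypot(cell.x_px - cx, cell.y_px - cy))
        if dist + dia / 2.0 > r_samp:
            continue
        has1, has2 = m1 in cell.markers, m2 in cell.markers
        if has1 and has2:
            counts["double"] += 1
        elif has1:
            counts[f"only_{m1}"] += 1
        elif has2:
            counts[f"only_{m2}"] += 1
    counts["total"] = counts[f"only_{m1}"] + counts[f"only_{m2}"] + counts["double"]
    return counts


def axon_colabel(
    marks_a: Sequence[CellMark] | np.ndarray,
    marks_b: Sequence[CellMark] | np.ndarray,
    roi_square_um: tuple[float, float, float, float] = (0.0, 0.0, 20.0, 20.0),
    tolerance_um: float = DEFAULT_AXON_TOLERANCE_UM,
) -> tuple[MatchResult, dict[str, float]]:
    """Axon co-labeling (e.g. S100 vs MBP) restricted to a square region.

    ``roi_square_um = (x0, y0, w, h)``; one mark = one axon cross-profile.
    Marks are clipped to the square, matched with the axon-scale tolerance,
    and reported as only-A / only-B / double percentages.
    """
    x0, y0, w, h = roi_square_um

    def clip(marks):
        p = _coords(marks)
        if len(p) == 0:
            return p
        keep = (p[:, 0] >= x0) & (p[:, 0] <= x0 + w) & (p[:, 1] >= y0) & (p[:, 1] <= y0 + h)
        return p[keep]

    result = match_marks(clip(marks_a), clip(marks_b), tolerance_um)
    return result, match_fractions(result)
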