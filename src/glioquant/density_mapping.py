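"""Counts, areas, densities and normalized 5 %-bin density maps.

The density map discretizes each nucleus into a 20x20 grid of 5 %
increments of its normalized bounding box, counts marked somata per bin,
and scales the counts by the section's maximum bin so values lie in
[0, 1].  Per-section grids are then averaged per nucleus and age group,
and rendered as gray values (darker = denser).  The grid size is fixed at
20x20 so that cross-section averaging is always well defined.

Grid layout: ``bins[iy, ix]`` with ``ix`` the 5 %-bin index along the
medio-lateral (x) axis and ``iy`` along the ventro-dorsal (y) axis;
``iy = 0`` is ventral.  :func:`render_grid` flips rows so dorsal appears
at the top of the image, the usual display orientation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from glioquant.geometry_io import CellMark, NucleusROI, SectionFrame, point_in_roi

logger = logging.getLogger("glioquant")

GRID_N = 20  # 100 % / 5 % increments
BIN_WIDTH_PERCENT = 5


@dataclass(frozen=True)
class DensityGrid:
    """20x20 normalized density map of one section (or an average)."""

    section_id: str
    nucleus: str
    bins: np.ndarray  # (20, 20), values in [0, 1]
    n_marks: int
    bin_width_percent: int = BIN_WIDTH_PERCENT

    def __post_init__(self) -> None:
        b = np.asarray(self.bins, dtype=float)
        if b.shape != (GRID_N, GRID_N):
            raise ValueError(f"density grid must be {GRID_N}x{GRID_N}")
        if b.min() < 0 or b.max() > 1 + 1e-12:
            raise ValueError("density grid values must lie in [0, 1]")
        object.__setattr__(self, "bins", b)


@dataclass(frozen=True)
class DensityRecord:
    """Count / area / density summary of one nucleus in one section."""

    section_id: str
    nucleus: str
    count: int
    area_mm2: float

    @property
    def density_per_mm2(self) -> float:
        return self.count / self.area_mm2


def count_in_nucleus(marks: Sequence[CellMark], roi: NucleusROI) -> int:
    """Number of marks inside (or on the boundary of) the nucleus polygon."""
    return sum(point_in_roi(m, roi) for m in marks)


def density(count: int, area_mm2: float) -> float:
    """Cells per mm^2: count divided by the section's nucleus area."""
    if area_mm2 <= 0:
        raise ValueError("area must be > 0")
    return count / area_mm2


def density_record(
    marks: Sequence[CellMark], roi: NucleusROI, frame: SectionFrame
) -> DensityRecord:
    from glioquant.geometry_io import polygon_area

    _, area_mm2 = polygon_area(roi, frame)
    return DensityRecord(roi.section_id, roi.nucleus, count_in_nucleus(marks, roi), area_mm2)


def bin_marks(normalized: np.ndarray) -> np.ndarray:
    """Count normalized marks into the 20x20 grid of 5 % increments.

    Bins are half-open ``[5k, 5k + 5)`` except the last, which is closed
    at 100 so that marks on the far boundary are kept.  Returns an integer
    grid ``counts[iy, ix]`` whose sum equals the number of marks.
    """
    normalized = np.asarray(normalized, dtype=float)
    if normalized.size == 0:
        return np.zeros((GRID_N, GRID_N), dtype=int)
    if normalized.min() < 0 or normalized.max() > 100:
        raise ValueError("normalized coordinates must lie in [0, 100]")
    edges = np.arange(0, 101, BIN_WIDTH_PERCENT, dtype=float)
    counts, _, _ = np.histogram2d(normalized[:, 1], normalized[:, 0], bins=(edges, edges))
    return counts.astype(int)


def normalize_grid(counts: np.ndarray, section_id: str, nucleus: str) -> DensityGrid:
    """Scale a count grid by its maximum bin: the section's densest 5 % bin
    becomes 1 and all values lie in [0, 1]."""
    counts = np.asarray(counts, dtype=float)
    peak = counts.max()
    if peak <= 0:
        raise ValueError(
            f"{nucleus}/{section_id}: cannot normalize an empty section "
            "(exclude zero-mark sections upstream)"
        )
    return DensityGrid(section_id, nucleus, counts / peak, n_marks=int(counts.sum()))


def grid_from_marks(
    marks: Sequence[CellMark], roi: NucleusROI
) -> DensityGrid:
    """Full per-section map: filter to the polygon, normalize coordinates,
    bin, scale by the maximum bin."""
    from glioquant.geometry_io import normalize_coordinates

    inside = [m for m in marks if point_in_roi(m, roi)]
    dropped = len(marks) - len(inside)
    if dropped:
        logger.info(
            "%s/%s: %d mark(s) outside the ROI polygon excluded from binning",
            roi.nucleus, roi.section_id, dropped,
        )
    if not inside:
        raise ValueError(f"{roi.nucleus}/{roi.section_id}: no marks inside ROI")
    counts = bin_marks(normalize_coordinates(inside, roi))
    return normalize_grid(counts, roi.section_id, roi.nucleus)


def average_grids(grids: Sequence[DensityGrid]) -> DensityGrid:
    """Element-wise mean of per-section grids of one nucleus.

    The average's maximum can be < 1 when sections peak in different bins.
    """
    if not grids:
        raise ValueError("need at least one grid")
    nuclei = {g.nucleus for g in grids}
    if len(nuclei) > 1:
        raise ValueError(f"cannot average grids of different nuclei: {sorted(nuclei)}")
    mean = np.mean([g.bins for g in grids], axis=0)
    return DensityGrid("average", grids[0].nucleus, mean, n_marks=sum(g.n_marks for g in grids))


def render_grid(grid: DensityGrid) -> np.ndarray:
    """Render as an 8-bit grayscale image: density 1 -> 0 (black),
    0 -> 255 (white), linear in between, rounded half-up.

    Rows are flipped so that dorsal (high ry) is at the top of the image.
    """
    gray = np.floor(255.0 * (1.0 - grid.bins) + 0.5)
    return np.flipud(gray).astype(np.uint8)
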