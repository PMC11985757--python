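"""Single-cell oligodendrocyte process morphometry.

A traced cell consists of a soma and a set of process polylines, each
classified as *primary* (emerging directly from the soma), *secondary*
(emerging from a primary) or *blind* (ending abruptly without forming a
myelin sheath).  Per process the pipeline measures arc length,
orientation to the medio-lateral axis, and the 5-point mean diameter
(width at the centers of five equal sub-segments, i.e. arc-length
fractions 0.1, 0.3, 0.5, 0.7, 0.9).  Per cell, the coverage polygon is
the convex hull of all trace points, with area and minimum/maximum Feret
(caliper) diameters by rotating calipers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.ndimage import map_coordinates
from scipy.spatial import ConvexHull

logger = logging.getLogger("glioquant")

DIAMETER_FRACTIONS = (0.1, 0.3, 0.5, 0.7, 0.9)
PROCESS_KINDS = ("primary", "secondary", "blind")


class TopologyError(ValueError):
    """A trace is attached to nothing, or a parent reference is invalid."""


@dataclass(frozen=True)
class ProcessTrace:
    """One traced oligodendrocyte process (coordinates in um).

    ``width_samples`` holds (arc-length fraction, width um) pairs; a NaN
    width marks a position where overlapping processes made the width
    unmeasurable.
    """

    cell_id: str
    trace_id: str
    kind: str
    polyline: np.ndarray  # (n, 2) um
    parent_id: str | None = None
    width_samples: tuple[tuple[float, float], ...] | None = None
    myelinating: bool = False

    def __post_init__(self) -> None:
        if self.kind not in PROCESS_KINDS:
            raise ValueError(f"unknown process kind {self.kind!r}")
        pl = np.asarray(self.polyline, dtype=float)
        if pl.ndim != 2 or pl.shape[0] < 2 or pl.shape[1] != 2:
            raise ValueError("polyline needs >= 2 points of (x, y)")
        object.__setattr__(self, "polyline", pl)
        if self.width_samples is not None:
            ws = tuple((float(f), float(w)) for f, w in self.width_samples)
            for f, w in ws:
                if not 0.0 <= f <= 1.0:
                    raise ValueError("width sample positions are arc-length fractions in [0,1]")
                if not (np.isnan(w) or w > 0):
                    raise ValueError("widths must be > 0 (NaN = unmeasurable)")
            object.__setattr__(self, "width_samples", ws)
        if self.kind == "secondary" and self.parent_id is None:
            raise TopologyError(f"secondary process {self.trace_id} has no parent primary")


@dataclass(frozen=True)
class OligoCell:
    """Soma plus attached process traces."""

    cell_id: str
    soma_center: tuple[float, float]
    soma_diameter_um: float
    traces: tuple[ProcessTrace, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "traces", tuple(self.traces))
        primaries = {t.trace_id for t in self.traces if t.kind == "primary"}
        for t in self.traces:
            if t.kind == "secondary" and t.parent_id not in primaries:
                raise TopologyError(
                    f"secondary {t.trace_id} references missing primary {t.parent_id!r}"
                )


@dataclass(frozen=True)
class CoverageRecord:
    """Convex coverage polygon of one cell with Feret descriptors."""

    cell_id: str
    vertices: np.ndarray  # hull vertices, ccw
    area_um2: float
    feret_min_um: float
    feret_max_um: float
    feret_angle_deg: float  # direction of the maximum Feret, [0, 180)

    @property
    def shape_ratio(self) -> float:
        """Roundness: minimum / maximum Feret (1 for a circle)."""
        return self.feret_min_um / self.feret_max_um


def classify_processes(cell: OligoCell) -> dict[str, int]:
    """Counts per process class for one cell.

    ``all`` = primary + secondary + blind; ``myelinating`` counts traces
    whose myelination was verified on at least one cross-profile chip.
    """
    counts = {k: 0 for k in PROCESS_KINDS}
    myelinating = 0
    for t in cell.traces:
        counts[t.kind] += 1
        if t.myelinating:
            myelinating += 1
    counts["myelinating"] = myelinating
    counts["all"] = counts["primary"] + counts["secondary"] + counts["blind"]
    return counts


def process_length(trace: ProcessTrace) -> float:
    """Arc length of the process polyline in um."""
    seg = np.diff(trace.polyline, axis=0)
    return float(np.hypot(seg[:, 0], seg[:, 1]).sum())


def process_orientation(trace: ProcessTrace) -> float:
    """Angle of the process chord (first to last point) to the
    medio-lateral (x) axis, folded to [0, 90] degrees (undirected)."""
    dx, dy = trace.polyline[-1] - trace.polyline[0]
    if dx == 0 and dy == 0:
        raise ValueError(f"{trace.trace_id}: zero-length chord, orientation undefined")
    ang = np.degrees(np.arctan2(dy, dx)) % 180.0
    return float(min(ang, 180.0 - ang))


def process_diameter(trace: ProcessTrace) -> float:
    """5-point mean diameter in um.

    The process is divided into five equal sub-segments and the width is
    read at each center (arc-length fractions 0.1 ... 0.9) by linear
    interpolation of ``width_samples``.  Where a center falls in an
    unmeasurable (NaN) region — processes overlapping — the width of the
    nearest measurable sample on the same trace is substituted.  With no
    measurable sample at all the diameter is NaN (missing), logged.
    """
    if not trace.width_samples:
        raise ValueError(f"{trace.trace_id}: no width samples; use width_from_image instead")
    fr = np.array([f for f, _ in trace.width_samples])
    wd = np.array([w for _, w in trace.width_samples])
    order = np.argsort(fr)
    fr, wd = fr[order], wd[order]
    valid = ~np.isnan(wd)
    if not valid.any():
        logger.warning("%s: no measurable width position, diameter missing", trace.trace_id)
        return float("nan")
    widths = []
    for f in DIAMETER_FRACTIONS:
        w = np.interp(f, fr, wd)
        if np.isnan(w) or _bracketed_by_nan(f, fr, wd):
            nearest = np.argmin(np.abs(fr[valid] - f))
            w = wd[valid][nearest]
        widths.append(w)
    return float(np.mean(widths))


def _bracketed_by_nan(f: float, fr: np.ndarray, wd: np.ndarray) -> bool:
    """True if linear interpolation at f touches a NaN sample."""
    i = np.searchsorted(fr, f)
    lo = max(i - 1, 0)
    hi = min(i, len(fr) - 1)
    if fr[hi] == f:
        return bool(np.isnan(wd[hi]))
    return bool(np.isnan(wd[lo]) or np.isnan(wd[hi]))


def width_from_image(
    image: np.ndarray,
    point: tuple[float, float],
    tangent: tuple[float, float],
    pixel_size_um: float,
    half_length_um: float = 2.8,
    n_samples: int = 61,
) -> float:
    """Process width at one position measured on an image, as the full
    width at half maximum of the intensity profile perpendicular to the
    local tangent (profile half-length 2.8 um, matching the 5.55 um
    verification chips).  Background is the minimum of the profile ends.
    """
    t = np.asarray(tangent, dtype=float)
    t = t / np.hypot(*t)
    normal = np.array([-t[1], t[0]])
    s = np.linspace(-half_length_um, half_length_um, n_samples)
    pts_um = np.asarray(point) + s[:, None] * normal
    pts_px = pts_um / pixel_size_um
    # map_coordinates wants (row, col) = (y, x)
    prof = map_coordinates(
        np.asarray(image, dtype=float), [pts_px[:, 1], pts_px[:, 0]], order=1, mode="nearest"
    )
    k = max(1, n_samples // 10)
    background = min(prof[:k].mean(), prof[-k:].mean())
    peak = prof.max()
    if peak <= background:
        return float("nan")
    half = background + (peak - background) / 2.0
    above = prof >= half
    idx = np.nonzero(above)[0]
    left, right = idx[0], idx[-1]
    # sub-sample crossings by linear interpolation
    ds = s[1] - s[0]
    x_left = s[left]
    if left > 0:
        x_left = s[left - 1] + ds * (half - prof[left - 1]) / (prof[left] - prof[left - 1])
    x_right = s[right]
    if right < n_samples - 1:
        x_right = s[right] + ds * (prof[right] - half) / (prof[right] - prof[right + 1])
    return float(x_right - x_left)


# ---------------------------------------------------------------------------
# coverage polygon and Feret descriptors


def _feret_extremes(hull_pts: np.ndarray) -> tuple[float, float, float]:
    """(feret_min, feret_max, feret_angle_deg) by rotating calipers.

    feret_max is attained by a pair of hull vertices; feret_min is
    perpendicular to some hull edge.  The Feret angle is the direction of
    the chord achieving feret_max, reported in [0, 180).
    """
    n = len(hull_pts)
    # maximum caliper: vertex pair diameter
    best = (0.0, 0.0)
    for i in range(n):
        d = hull_pts[i + 1 :] - hull_pts[i]
        if len(d) == 0:
            continue
        dist = np.hypot(d[:, 0], d[:, 1])
        j = int(np.argmax(dist))
        if dist[j] > best[0]:
            ang = np.degrees(np.arctan2(d[j, 1], d[j, 0])) % 180.0
            best = (float(dist[j]), float(ang))
    feret_max, feret_angle = best
    # minimum caliper: min over edges of max vertex distance to edge line
    feret_min = np.inf
    for i in range(n):
        p, q = hull_pts[i], hull_pts[(i + 1) % n]
        e = q - p
        norm = np.hypot(*e)
        if norm == 0:
            continue
        nvec = np.array([-e[1], e[0]]) / norm
        width = np.abs((hull_pts - p) @ nvec).max()
        feret_min = min(feret_min, float(width))
    return feret_min, feret_max, feret_angle


def coverage(cell: OligoCell) -> CoverageRecord:
    """Coverage polygon of one cell: convex hull of all trace points,
    shoelace area and caliper Feret min/max/angle."""
    pts = np.vstack([t.polyline for t in cell.traces])
    try:
        hull = ConvexHull(pts)
    except Exception as exc:  # qhull raises on degenerate (collinear) input
        raise ValueError(f"{cell.cell_id}: degenerate (collinear) cell, no coverage polygon") from exc
    hull_pts = pts[hull.vertices]  # ccw
    area = float(hull.volume)  # 2-D ConvexHull: volume = area
    feret_min, feret_max, feret_angle = _feret_extremes(hull_pts)
    return CoverageRecord(cell.cell_id, hull_pts, area, feret_min, feret_max, feret_angle)


def cell_summary(cell: OligoCell) -> dict[str, float]:
    """Per-cell morphometry row: process counts, mean length / diameter /
    orientation over measurable processes, and coverage descriptors."""
    counts = classify_processes(cell)
    lengths = [process_length(t) for t in cell.traces]
    orientations = []
    for t in cell.traces:
        try:
            orientations.append(process_orientation(t))
        except ValueError:
            pass
    diameters = [
        process_diameter(t) for t in cell.traces if t.width_samples
    ]
    diameters = [d for d in diameters if not np.isnan(d)]
    row: dict[str, float] = {f"n_{k}": v for k, v in counts.items()}
    row["mean_length_um"] = float(np.mean(lengths)) if lengths else float("nan")
    row["mean_orientation_deg"] = float(np.mean(orientations)) if orientations else float("nan")
    row["mean_diameter_um"] = float(np.mean(diameters)) if diameters else float("nan")
    try:
        cov = coverage(cell)
        row["coverage_area_um2"] = cov.area_um2
        row["feret_min_um"] = cov.feret_min_um
        row["feret_max_um"] = cov.feret_max_um
        row["shape_ratio"] = cov.shape_ratio
        row["feret_angle_deg"] = cov.feret_angle_deg
    except ValueError:
        row["coverage_area_um2"] = float("nan")
    return row
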