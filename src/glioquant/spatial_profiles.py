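"""1-D profiles along the tonotopic axis, line scans and the myelin detector.

Three kinds of profile are produced:

* **Density-map profiles** — slices through a 20x20 normalized density
  map, either as a straight band (MNTB, MSO, dLSO, control) or along a
  curved path that follows the LSO's two limbs.  Profiles are sampled at
  the bin centers (2.5, 7.5, ..., 97.5 %); the averaging band spans the
  central 50 % of the orthogonal axis and may be shifted by up to +-10 %.
* **Image line scans** — per-channel column means over a rectangle placed
  on the MSO, reported in um from the medial edge; left-hemisphere scans
  are reversed so every profile runs medial -> lateral.
* **Myelin cross-profiles** — a short intensity profile taken across a
  process from a 5.55 x 5.55 um chip; a myelinated axon appears as two
  bright walls flanking a dim lumen.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.signal import find_peaks

from glioquant.density_mapping import GRID_N, DensityGrid
from glioquant.stats_reporting import GroupedMeasurements, TestReport, dispatch_test

BIN_CENTERS = np.arange(GRID_N) * 5.0 + 2.5  # 2.5, 7.5, ..., 97.5


@dataclass(frozen=True)
class IntensityProfile:
    """A 1-D intensity profile with its sample locations.

    ``locations`` are relative positions in % for density-map profiles,
    or um from the medial edge for image line scans.
    """

    values: np.ndarray
    locations: np.ndarray
    axis: str = "medio-lateral"
    source: str = "density-map"  # "density-map" | "image-channel"
    section_id: str = ""
    channel: str | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        loc = np.asarray(self.locations, dtype=float)
        if v.shape != loc.shape:
            raise ValueError("values and locations must have equal length")
        if loc.size >= 2 and not np.all(np.diff(loc) > 0):
            raise ValueError("locations must be strictly increasing")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "locations", loc)

    def window_mean(self, lo: float, hi: float) -> float:
        """Mean intensity over samples with location in [lo, hi]."""
        sel = (self.locations >= lo) & (self.locations <= hi)
        if not sel.any():
            raise ValueError(f"no samples in window [{lo}, {hi}]")
        return float(self.values[sel].mean())


@dataclass(frozen=True)
class CurvedPath:
    """Polyline of control points in normalized (0-100 %) coordinates.

    Used for the LSO, whose tonotopic axis bends dorsomedial -> ventral ->
    dorsolateral; the transverse averaging window covers
    ``local_width_percent`` of the frame at each position.
    """

    points: tuple[tuple[float, float], ...]
    local_width_percent: float = 30.0

    def __post_init__(self) -> None:
        pts = tuple((float(x), float(y)) for x, y in self.points)
        object.__setattr__(self, "points", pts)
        if len(pts) < 2:
            raise ValueError("path needs at least 2 control points")
        arr = np.asarray(pts)
        if arr.min() < 0 or arr.max() > 100:
            raise ValueError("path must stay within the [0, 100]^2 frame")


def band_profile(
    grid: DensityGrid,
    axis: str = "medio-lateral",
    center_shift_percent: float = 0.0,
    band_width_percent: float = 50.0,
) -> IntensityProfile:
    """Straight-band profile through a density map.

    For profile axis ``u`` the intensity at each of the 20 bin centers is
    the mean normalized density over the orthogonal band spanning the
    central ``band_width_percent`` (default 50 %, i.e. 25-75 %) of the
    orthogonal axis; the band center may be shifted by up to +-10 %.

    ``axis``: ``"medio-lateral"`` profiles along x (averaging over y);
    ``"dorso-ventral"`` profiles along y (averaging over x).
    """
    if abs(center_shift_percent) > 10:
        raise ValueError("band center shift limited to +-10 %")
    center = 50.0 + center_shift_percent
    lo, hi = center - band_width_percent / 2.0, center + band_width_percent / 2.0
    if lo < 0 or hi > 100:
        raise ValueError(f"band [{lo}, {hi}] leaves the 0-100 % frame")
    in_band = (BIN_CENTERS >= lo) & (BIN_CENTERS <= hi)
    if axis == "medio-lateral":
        values = grid.bins[in_band, :].mean(axis=0)
    elif axis == "dorso-ventral":
        values = grid.bins[:, in_band].mean(axis=1)
    else:
        raise ValueError(f"unknown profile axis {axis!r}")
    return IntensityProfile(values, BIN_CENTERS.copy(), axis=axis, section_id=grid.section_id)


def _resample_path(points: np.ndarray, fractions: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Points and unit tangents at given arc-length fractions of a polyline."""
    seg = np.diff(points, axis=0)
    seg_len = np.hypot(seg[:, 0], seg[:, 1])
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    total = cum[-1]
    if total <= 0:
        raise ValueError("degenerate path of zero length")
    s = fractions * total
    xy = np.column_stack(
        [np.interp(s, cum, points[:, 0]), np.interp(s, cum, points[:, 1])]
    )
    # tangent of the segment each sample falls in
    idx = np.clip(np.searchsorted(cum, s, side="right") - 1, 0, len(seg_len) - 1)
    tangents = seg[idx] / seg_len[idx, None]
    return xy, tangents


def curved_profile(grid: DensityGrid, path: CurvedPath) -> IntensityProfile:
    """Profile along a curved path through a density map.

    The path is arc-length parameterized to 0-100 %; 20 samples are taken
    at fractions 2.5, 7.5, ..., 97.5 %.  At each sample the intensity is
    the mean of grid bins whose centers fall within the transverse window:
    half-width ``local_width_percent / 2`` perpendicular to the local
    tangent and half a sample spacing (2.5 % of path length) along it.
    """
    pts = np.asarray(path.points, dtype=float)
    fractions = BIN_CENTERS / 100.0
    samples, tangents = _resample_path(pts, fractions)

    # all bin centers as (x, y) pairs
    cx, cy = np.meshgrid(BIN_CENTERS, BIN_CENTERS)  # cx[iy, ix] = x center
    centers = np.column_stack([cx.ravel(), cy.ravel()])
    dens = grid.bins.ravel()

    seg = np.diff(pts, axis=0)
    path_len = np.hypot(seg[:, 0], seg[:, 1]).sum()
    half_trans = path.local_width_percent / 2.0
    half_tang = 0.025 * path_len  # half the 5 %-of-arc-length sample spacing

    values = np.empty(GRID_N)
    for i, (p, t) in enumerate(zip(samples, tangents)):
        d = centers - p
        along = d @ t
        across = d @ np.array([-t[1], t[0]])
        sel = (np.abs(across) <= half_trans) & (np.abs(along) <= half_tang)
        if not sel.any():
            raise ValueError("transverse window contains no grid bins")
        values[i] = dens[sel].mean()
    return IntensityProfile(
        values, BIN_CENTERS.copy(), axis="curved-path", section_id=grid.section_id
    )


def default_curved_path(roi, n_control_points: int = 12,
                        local_width_percent: float = 30.0) -> CurvedPath:
    """Derive a default curved path as the medial axis of an ROI polygon.

    The freehand path through a bent nucleus (LSO) is user territory; this
    helper offers a reproducible default: the polygon is rasterized on the
    normalized 0-100 % frame, its medial-axis skeleton extracted, and the
    skeleton ordered into a polyline by walking from an endpoint, then
    subsampled to ``n_control_points``.
    """
    from shapely.geometry import Point as _Pt
    from skimage.morphology import medial_axis

    poly = roi.polygon
    xmin, ymin, xmax, ymax = roi.bbox()
    w, h = xmax - xmin, ymax - ymin
    # raster preserves the ROI's aspect so the skeleton is anatomical
    if w >= h:
        nx, ny = 101, max(int(round(101 * h / w)), 5)
    else:
        ny, nx = 101, max(int(round(101 * w / h)), 5)
    xs = np.linspace(xmin, xmax, nx)
    ys = np.linspace(ymin, ymax, ny)
    mask = np.zeros((ny, nx), dtype=bool)
    for iy, y in enumerate(ys):
        for ix, x in enumerate(xs):
            mask[iy, ix] = poly.covers(_Pt(x, y))
    # pad so the skeleton sees background even when the ROI fills its bbox
    skel = medial_axis(np.pad(mask, 1))[1:-1, 1:-1]
    pix = np.column_stack(np.nonzero(skel))  # (row, col)
    if len(pix) < 2:
        raise ValueError("ROI too thin to derive a medial-axis path")
    # order by nearest-neighbor walk from an extremal skeleton pixel
    start = int(np.argmax(np.abs(pix - pix.mean(axis=0)).sum(axis=1)))
    remaining = list(range(len(pix)))
    order = [remaining.pop(start)]
    while remaining:
        last = pix[order[-1]]
        d = np.abs(pix[remaining] - last).sum(axis=1)
        k = int(np.argmin(d))
        if d[k] > 5:  # disconnected side branch: stop the walk
            break
        order.append(remaining.pop(k))
    path_pix = pix[order]
    idx = np.linspace(0, len(path_pix) - 1, n_control_points).astype(int)
    pts = tuple(
        (
            float(100.0 * path_pix[i, 1] / (nx - 1)),  # col -> x %
            float(100.0 * path_pix[i, 0] / (ny - 1)),  # row -> y %
        )
        for i in idx
    )
    return CurvedPath(pts, local_width_percent=local_width_percent)


@dataclass(frozen=True)
class EdgeComparison:
    """Result of comparing the two edge regions of a set of profiles."""

    low_means: np.ndarray  # per-section mean over [5, 15] %
    high_means: np.ndarray  # per-section mean over [85, 95] %
    report: TestReport = field(repr=False)

    @property
    def low_mean(self) -> float:
        return float(self.low_means.mean())

    @property
    def high_mean(self) -> float:
        return float(self.high_means.mean())

    @property
    def p_value(self) -> float:
        return self.report.p_value

    @property
    def test_name(self) -> str:
        return self.report.test_name


def edge_compare(
    profiles: Sequence[IntensityProfile],
    low_window: tuple[float, float] = (5.0, 15.0),
    high_window: tuple[float, float] = (85.0, 95.0),
) -> EdgeComparison:
    """Compare average intensities of the two edge regions across sections.

    Per section, the profile is averaged over 5-15 % (medial / dorsal /
    dorsomedial) and 85-95 % (lateral / ventral / dorsolateral) of the
    relative location; the two per-section samples then go through the
    normality-gated two-group dispatch.  With bin-center sampling, [5, 15]
    covers the bins centered at 7.5 and 12.5 %.
    """
    if len(profiles) < 2:
        raise ValueError("edge comparison needs at least 2 sections")
    low = np.array([p.window_mean(*low_window) for p in profiles])
    high = np.array([p.window_mean(*high_window) for p in profiles])
    report = dispatch_test(
        GroupedMeasurements(
            groups=[("low-edge", low.tolist()), ("high-edge", high.tolist())],
            measure="normalized intensity",
        )
    )
    return EdgeComparison(low, high, report)


def line_scan(
    image: np.ndarray,
    rect: tuple[int, int, int, int],
    channels: Mapping[str, int],
    pixel_size_um: float,
    hemisphere: str = "right",
    section_id: str = "",
) -> dict[str, IntensityProfile]:
    """Per-channel fluorescence line scan over a rectangle.

    ``image`` is ``(C, H, W)`` (or ``(H, W)`` for one channel);
    ``rect = (x, y, w, h)`` in pixels with the long axis medio-lateral.
    Each profile value is the mean over the rectangle's height of one
    column; locations are um from the medial edge.  Left-hemisphere scans
    are reversed so the output always runs medial -> lateral.
    """
    if image.ndim == 2:
        image = image[None, ...]
    x, y, w, h = rect
    _, H, W = image.shape
    if x < 0 or y < 0 or x + w > W or y + h > H or w <= 0 or h <= 0:
        raise ValueError(f"rectangle {rect} exceeds image bounds {(W, H)}")
    locations = (np.arange(w) + 0.5) * pixel_size_um
    out: dict[str, IntensityProfile] = {}
    for name, ci in channels.items():
        cols = image[ci, y : y + h, x : x + w].mean(axis=0, dtype=float)
        if hemisphere == "left":
            cols = cols[::-1]
        out[name] = IntensityProfile(
            cols, locations, axis="medio-lateral", source="image-channel",
            section_id=section_id, channel=name,
        )
    return out


def chip_profile(chip: np.ndarray, axis: int = 0) -> np.ndarray:
    """Cross-profile of a process chip: mean along the process axis
    (default: process runs vertically, average over rows)."""
    return np.asarray(chip, dtype=float).mean(axis=axis)


def detect_myelin(
    profile: np.ndarray,
    r_center: float = 0.6,
    r_peak: float = 2.0,
    prominence_fraction: float = 0.10,
    smooth_sigma: float = 1.0,
) -> bool:
    """Decide whether a cross-profile shows a myelinated axon.

    A myelin sheath cut transversely shows two bright walls around a dim
    lumen: the profile must have two dominant local maxima with the
    minimum between them near the profile center, center intensity at most
    ``r_center`` x the lower peak, and both peaks at least ``r_peak`` x
    the background (median of the outer 20 % of samples on each side).
    A filled (unmyelinated) process gives a single plateau; background
    gives no peaks.  The profile is lightly smoothed (Gaussian,
    ``smooth_sigma`` samples) before peak finding.
    """
    profile = np.asarray(profile, dtype=float)
    if profile.size < 7:
        raise ValueError("cross-profile needs at least 7 samples")
    if not profile.any():
        return False
    p = gaussian_filter1d(profile, smooth_sigma) if smooth_sigma > 0 else profile
    n = p.size
    dyn = p.max() - p.min()
    if dyn <= 0:
        return False
    k = max(1, int(round(0.2 * n)))
    background = float(np.median(np.concatenate([p[:k], p[-k:]])))

    peaks, props = find_peaks(p, prominence=prominence_fraction * dyn)
    if len(peaks) < 2:
        return False
    # the two most prominent maxima are the candidate walls
    order = np.argsort(props["prominences"])[::-1]
    left, right = sorted(peaks[order[:2]])
    valley_idx = left + int(np.argmin(p[left : right + 1]))
    valley = p[valley_idx]
    # lumen must sit in the central half of the chip
    if not (0.25 * n <= valley_idx <= 0.75 * n):
        return False
    lower_peak = min(p[left], p[right])
    if valley > r_center * lower_peak:
        return False
    if background > 0 and lower_peak < r_peak * background:
        return False
    return True
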