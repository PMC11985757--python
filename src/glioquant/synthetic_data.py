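"""Seeded generators for every input class the pipeline consumes.

The study's raw microscopy data are not deposited, so recovery tests run
on synthetic inputs that emulate its structure at realistic scales:
nucleus bounding boxes of 150-500 um, soma diameters around 17 um,
myelin verification chips of 5.55 um, and an MSO line-scan rectangle of
359 x 72 um.  Every generator takes an explicit seed (bit-reproducible)
and returns, alongside the data, a machine-readable ``truth`` dict
sufficient to score the downstream operation without re-deriving ground
truth.

Cell counts per nucleus section are fixed-n by default (the study
reports counts per section); a Poisson mode exists for density-recovery
tests.
"""

from __future__ import annotations

import numpy as np
from shapely.geometry import Point, Polygon

from glioquant.colocalization import CalyxScene
from glioquant.geometry_io import CellMark, NucleusROI
from glioquant.morphometry import OligoCell, ProcessTrace


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def _polygon_of(roi) -> Polygon:
    return roi.polygon if isinstance(roi, NucleusROI) else Polygon(roi)


# ---------------------------------------------------------------------------
# point patterns


def gen_points(
    roi,
    n: int | None = None,
    rate_per_mm2: float | None = None,
    gradient_axis: str = "x",
    gradient_ratio: float = 1.0,
    marker: str = "Olig2",
    section_id: str = "synthetic",
    nucleus: str = "MNTB",
    pixel_size_um: float = 1.0,
    seed=0,
) -> tuple[list[CellMark], dict]:
    """Sample a soma-center point pattern inside a nucleus polygon.

    Exactly one of ``n`` (fixed count, multinomial placement) or
    ``rate_per_mm2`` (homogeneous Poisson count) must be given.  The
    intensity is linear along the chosen normalized axis, rising from 1
    at 0 % to ``gradient_ratio`` at 100 % (lateral:medial density ratio;
    1 = homogeneous), realized by rejection sampling.
    """
    if (n is None) == (rate_per_mm2 is None):
        raise ValueError("give exactly one of n or rate_per_mm2")
    if gradient_ratio <= 0:
        raise ValueError("gradient ratio must be > 0")
    if gradient_axis not in ("x", "y"):
        raise ValueError("gradient axis must be 'x' or 'y'")
    rng = _rng(seed)
    poly = _polygon_of(roi)
    xmin, ymin, xmax, ymax = poly.bounds
    if rate_per_mm2 is not None:
        if rate_per_mm2 <= 0:
            raise ValueError("rate must be > 0")
        area_mm2 = poly.area * pixel_size_um**2 * 1e-6
        n = int(rng.poisson(rate_per_mm2 * area_mm2))
    assert n is not None

    hi = max(1.0, gradient_ratio)
    pts: list[tuple[float, float]] = []
    while len(pts) < n:
        m = max(4 * (n - len(pts)), 64)
        xs = rng.uniform(xmin, xmax, m)
        ys = rng.uniform(ymin, ymax, m)
        u = (xs - xmin) / (xmax - xmin) if gradient_axis == "x" else (ys - ymin) / (ymax - ymin)
        intensity = 1.0 + (gradient_ratio - 1.0) * u
        accept = rng.uniform(0, hi, m) < intensity
        for x, y, ok in zip(xs, ys, accept):
            if ok and poly.covers(Point(x, y)):
                pts.append((float(x), float(y)))
                if len(pts) == n:
                    break
    marks = [
        CellMark(section_id, nucleus, x, y, frozenset({marker})) for x, y in pts
    ]
    truth = {
        "kind": "points",
        "n": n,
        "gradient_axis": gradient_axis,
        "gradient_ratio": gradient_ratio,
        "rate_per_mm2": rate_per_mm2,
        "bbox": (xmin, ymin, xmax, ymax),
    }
    return marks, truth


# ---------------------------------------------------------------------------
# MSO tri-channel image


def gen_mso_image(
    width_um: float = 359.0,
    height_um: float = 72.0,
    pixel_size_um: float = 0.6,
    map2_center_um: float | None = None,
    map2_width_um: float = 40.0,
    vglut1_mode: str = "dendritic",
    vglut1_offset_um: float = 60.0,
    olig2_pattern: str = "uniform",
    noise_sigma: float = 5.0,
    base: float = 20.0,
    amplitude: float = 180.0,
    seed=0,
) -> tuple[np.ndarray, dict]:
    """Synthesize a 3-channel MSO-like banded image ``(3, H, W)``.

    Channel order: MAP2, VGluT1, Olig2.  MAP2 is a single Gaussian band
    (the central soma column) along x; VGluT1 is two flanking bands at
    ``map2_center +- vglut1_offset`` in ``"dendritic"`` mode (young) or a
    single somatic band in ``"perisomatic"`` mode (mature).  Olig2 is
    ``"uniform"``, or ``"border-accumulated"`` with puncta density peaking
    at the VGluT1 transition zones (young pattern), or ``"somatic"``
    following the MAP2 band (mature pattern).  Gaussian noise of sd
    ``noise_sigma`` is added; sigma = 0 gives a deterministic image.
    """
    if vglut1_mode not in ("dendritic", "perisomatic"):
        raise ValueError("vglut1_mode must be 'dendritic' or 'perisomatic'")
    if olig2_pattern not in ("uniform", "border-accumulated", "somatic"):
        raise ValueError("unknown olig2_pattern")
    rng = _rng(seed)
    W = int(round(width_um / pixel_size_um))
    H = int(round(height_um / pixel_size_um))
    if map2_center_um is None:
        map2_center_um = width_um / 2.0
    for c in (map2_center_um - map2_width_um, map2_center_um + map2_width_um):
        if not 0 <= c <= width_um:
            raise ValueError("MAP2 band leaves the image")
    if vglut1_mode == "dendritic" and (
        map2_center_um - vglut1_offset_um < 0 or map2_center_um + vglut1_offset_um > width_um
    ):
        raise ValueError("VGluT1 bands leave the image")

    x_um = (np.arange(W) + 0.5) * pixel_size_um

    def band(center, width):
        return np.exp(-0.5 * ((x_um - center) / width) ** 2)

    map2 = base + amplitude * band(map2_center_um, map2_width_um / 2.355)  # FWHM -> sigma
    if vglut1_mode == "dendritic":
        vglut1 = base + amplitude * (
            band(map2_center_um - vglut1_offset_um, map2_width_um / 2.355)
            + band(map2_center_um + vglut1_offset_um, map2_width_um / 2.355)
        )
        vglut1_centers = (
            map2_center_um - vglut1_offset_um,
            map2_center_um + vglut1_offset_um,
        )
    else:
        vglut1 = base + amplitude * band(map2_center_um, map2_width_um / 2.355)
        vglut1_centers = (map2_center_um,)
    if olig2_pattern == "uniform":
        olig2 = np.full(W, base + amplitude / 3.0)
    elif olig2_pattern == "somatic":
        olig2 = base + amplitude / 2.0 * band(map2_center_um, map2_width_um / 2.355)
    else:  # border-accumulated: peaks at the VGluT1 transition zones
        olig2 = np.full(W, float(base))
        for vc in vglut1_centers:
            for sgn in (-1.0, 1.0):
                olig2 = olig2 + amplitude / 2.0 * band(vc + sgn * map2_width_um / 2.0, 6.0)

    img = np.empty((3, H, W))
    for ci, row in enumerate((map2, vglut1, olig2)):
        img[ci] = row[None, :]
    if noise_sigma > 0:
        img = img + rng.normal(0.0, noise_sigma, img.shape)
    img = np.clip(img, 0, None)
    truth = {
        "kind": "mso_image",
        "pixel_size_um": pixel_size_um,
        "map2_center_um": map2_center_um,
        "vglut1_centers_um": vglut1_centers,
        "vglut1_mode": vglut1_mode,
        "olig2_pattern": olig2_pattern,
        "shape": (3, H, W),
    }
    return img, truth


# ---------------------------------------------------------------------------
# myelin verification chips


def gen_tube_chip(
    chip_size_um: float = 5.55,
    pixel_size_um: float = 0.15,
    outer_width_um: float = 2.0,
    wall_fraction: float = 0.25,
    filled: bool = False,
    background: float = 10.0,
    wall_intensity: float = 200.0,
    lumen_intensity: float = 20.0,
    snr: float = 10.0,
    seed=0,
) -> tuple[np.ndarray, dict]:
    """Synthesize one 5.55 x 5.55 um verification chip.

    The process runs vertically through the chip center.  A *hollow*
    chip has two bright walls (each ``wall_fraction`` of the outer width)
    flanking a dim lumen — the cross-section of a myelin sheath around an
    axon.  A *filled* chip is uniformly bright across the outer width —
    an unmyelinated process.  Gaussian noise of sd
    ``(wall_intensity - background) / snr`` is added.
    """
    if not 0.0 < wall_fraction < 0.5:
        raise ValueError("wall_fraction must be in (0, 0.5)")
    rng = _rng(seed)
    npx = int(round(chip_size_um / pixel_size_um))
    x_um = (np.arange(npx) + 0.5) * pixel_size_um - chip_size_um / 2.0
    half = outer_width_um / 2.0
    inner = half * (1.0 - 2.0 * wall_fraction)
    row = np.full(npx, background)
    if filled:
        row[np.abs(x_um) <= half] = wall_intensity
    else:
        row[np.abs(x_um) <= half] = lumen_intensity
        wall = (np.abs(x_um) <= half) & (np.abs(x_um) >= inner)
        row[wall] = wall_intensity
    chip = np.tile(row, (npx, 1))
    sigma = (wall_intensity - background) / snr
    if sigma > 0:
        chip = chip + rng.normal(0.0, sigma, chip.shape)
    truth = {
        "kind": "tube_chip",
        "filled": filled,
        "outer_width_um": outer_width_um,
        "wall_fraction": wall_fraction,
        "snr": snr,
        "template_row": row,
    }
    return chip, truth


# ---------------------------------------------------------------------------
# calyx scenes


def gen_calyx_scene(
    calyx_diameter_um: float = 13.0,
    n_cells: int = 8,
    p_s100_only: float = 0.05,
    p_olig2_only: float = 0.65,
    p_double: float = 0.30,
    r_max_um: float = 40.0,
    soma_diameter_mean_um: float = 17.0,
    soma_diameter_sd_um: float = 1.5,
    seed=0,
) -> tuple[CalyxScene, dict]:
    """Synthesize one calyx-proximity scene.

    ``n_cells`` somata are placed uniformly in the disc of radius
    ``r_max_um`` around the calyx center (area-uniform), with marker
    categories drawn from the given multinomial and soma diameters from a
    truncated normal around the 17 um mean.  Truth records each cell's
    planted category and whether its soma lies fully inside the sampling
    circle (computed independently from the generator's own geometry).
    """
    probs = (p_s100_only, p_olig2_only, p_double)
    if abs(sum(probs) - 1.0) > 1e-9:
        raise ValueError("marker probabilities must sum to 1")
    rng = _rng(seed)
    center = (0.0, 0.0)
    sampling_radius = (calyx_diameter_um + soma_diameter_mean_um) / 2.0
    cats = rng.choice(3, size=n_cells, p=probs)
    marker_sets = (frozenset({"S100"}), frozenset({"Olig2"}), frozenset({"S100", "Olig2"}))
    cat_names = ("only_S100", "only_Olig2", "double")
    cells, truth_cells = [], []
    for i in range(n_cells):
        r = r_max_um * np.sqrt(rng.uniform())
        theta = rng.uniform(0, 2 * np.pi)
        x, y = r * np.cos(theta), r * np.sin(theta)
        dia = float(np.clip(rng.normal(soma_diameter_mean_um, soma_diameter_sd_um), 8.0, 26.0))
        cells.append(
            CellMark("synthetic", "MNTB", x + 100.0, y + 100.0, marker_sets[cats[i]], dia)
        )
        truth_cells.append(
            {
                "category": cat_names[cats[i]],
                "distance_um": r,
                "soma_diameter_um": dia,
                "proximal": bool(r + dia / 2.0 <= sampling_radius),
            }
        )
    scene = CalyxScene((100.0, 100.0), calyx_diameter_um, tuple(cells))
    truth = {
        "kind": "calyx_scene",
        "probabilities": dict(zip(cat_names, probs)),
        "sampling_radius_um": sampling_radius,
        "cells": truth_cells,
    }
    return scene, truth


# ---------------------------------------------------------------------------
# co-labeling scenes


def gen_colabel_scene(
    n_cells: int = 30,
    p_double: float = 0.6,
    p_only_a: float = 0.2,
    p_only_b: float = 0.2,
    field_um: float = 72.0,
    jitter_sigma_um: float = 1.0,
    min_spacing_um: float = 8.0,
    seed=0,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Two overlaid point sets with a planted co-labeled fraction.

    Somata are placed with a minimum spacing (hard-core thinning, as real
    somata do not overlap); a planted fraction appears in both channels
    with independent Gaussian jitter of sd ``jitter_sigma_um`` per
    channel, the rest in one channel only.  Returns (marks_a, marks_b,
    truth) with coordinate arrays in um.
    """
    if abs(p_double + p_only_a + p_only_b - 1.0) > 1e-9:
        raise ValueError("category probabilities must sum to 1")
    rng = _rng(seed)
    centers: list[tuple[float, float]] = []
    attempts = 0
    while len(centers) < n_cells and attempts < 100000:
        attempts += 1
        x, y = rng.uniform(0, field_um, 2)
        if all((x - cx) ** 2 + (y - cy) ** 2 >= min_spacing_um**2 for cx, cy in centers):
            centers.append((float(x), float(y)))
    if len(centers) < n_cells:
        raise ValueError("field too crowded for requested n_cells at min_spacing")
    cats = rng.choice(3, size=n_cells, p=(p_double, p_only_a, p_only_b))
    a, b = [], []
    for (x, y), c in zip(centers, cats):
        if c in (0, 1):
            a.append((x + rng.normal(0, jitter_sigma_um), y + rng.normal(0, jitter_sigma_um)))
        if c in (0, 2):
            b.append((x + rng.normal(0, jitter_sigma_um), y + rng.normal(0, jitter_sigma_um)))
    truth = {
        "kind": "colabel_scene",
        "n_cells": n_cells,
        "planted_fractions": {"double": p_double, "only_A": p_only_a, "only_B": p_only_b},
        "n_double": int((cats == 0).sum()),
        "n_only_a": int((cats == 1).sum()),
        "n_only_b": int((cats == 2).sum()),
    }
    return np.asarray(a).reshape(-1, 2), np.asarray(b).reshape(-1, 2), truth


# ---------------------------------------------------------------------------
# oligodendrocyte cells


def gen_oligo_cell(
    n_primary: int = 4,
    n_secondary: int = 2,
    n_blind: int = 2,
    length_mean_um: float = 25.0,
    length_sd_um: float = 6.0,
    width_base_um: float = 1.2,
    width_tip_um: float = 0.6,
    orientations_deg: list[float] | None = None,
    myelinating_fraction: float = 1.0,
    soma_diameter_um: float = 17.0,
    cell_id: str = "synthetic-cell",
    n_points_per_trace: int = 11,
    seed=0,
) -> tuple[OligoCell, dict]:
    """Synthesize one traced oligodendrocyte with analytic ground truth.

    Primary processes radiate from the soma as straight chords (so the
    planted length, orientation and linear width taper are *exactly* the
    morphometric ground truth); secondaries branch from the midpoint of
    the first primaries; blind endings are short soma stubs without
    widths.  Truth records, per trace: kind, length, chord orientation
    folded to [0, 90], the analytic 5-point mean diameter, and the
    myelination flag; plus the exact class counts.
    """
    if n_secondary > 0 and n_primary == 0:
        raise ValueError("secondary processes need at least one primary")
    rng = _rng(seed)
    cx, cy = 0.0, 0.0
    r0 = soma_diameter_um / 2.0
    traces: list[ProcessTrace] = []
    truth_traces: list[dict] = []

    def taper_samples():
        fr = np.linspace(0.0, 1.0, 7)
        return tuple(
            (float(f), float(width_base_um + (width_tip_um - width_base_um) * f)) for f in fr
        )

    def analytic_5pt():
        fs = np.array([0.1, 0.3, 0.5, 0.7, 0.9])
        return float(np.mean(width_base_um + (width_tip_um - width_base_um) * fs))

    if orientations_deg is None:
        prim_angles = rng.uniform(0.0, 360.0, n_primary)
    else:
        if len(orientations_deg) != n_primary:
            raise ValueError("orientations_deg must have n_primary entries")
        prim_angles = np.asarray(orientations_deg, dtype=float)

    def straight(trace_id, kind, start, angle_deg, length, parent=None, widths=None, myel=False):
        rad = np.radians(angle_deg)
        d = np.array([np.cos(rad), np.sin(rad)])
        t = np.linspace(0.0, 1.0, n_points_per_trace)
        pl = np.asarray(start) + np.outer(t * length, d)
        return ProcessTrace(cell_id, trace_id, kind, pl, parent, widths, myel)

    for i, ang in enumerate(prim_angles):
        length = float(np.clip(rng.normal(length_mean_um, length_sd_um), 5.0, None))
        rad = np.radians(ang)
        start = (cx + r0 * np.cos(rad), cy + r0 * np.sin(rad))
        myel = bool(rng.uniform() < myelinating_fraction)
        tid = f"p{i}"
        traces.append(straight(tid, "primary", start, ang, length, widths=taper_samples(), myel=myel))
        folded = float(min(ang % 180.0, 180.0 - ang % 180.0))
        truth_traces.append(
            {
                "trace_id": tid, "kind": "primary", "length_um": length,
                "orientation_deg": folded, "diameter_um": analytic_5pt(),
                "myelinating": myel,
            }
        )
    for j in range(n_secondary):
        parent = traces[j % n_primary]
        mid = parent.polyline[len(parent.polyline) // 2]
        ang = float(rng.uniform(0.0, 360.0))
        length = float(np.clip(rng.normal(length_mean_um / 2.0, length_sd_um / 2.0), 3.0, None))
        myel = bool(rng.uniform() < myelinating_fraction)
        tid = f"s{j}"
        traces.append(
            straight(tid, "secondary", mid, ang, length, parent=parent.trace_id,
                     widths=taper_samples(), myel=myel)
        )
        folded = float(min(ang % 180.0, 180.0 - ang % 180.0))
        truth_traces.append(
            {
                "trace_id": tid, "kind": "secondary", "length_um": length,
                "orientation_deg": folded, "diameter_um": analytic_5pt(),
                "myelinating": myel,
            }
        )
    for k in range(n_blind):
        ang = float(rng.uniform(0.0, 360.0))
        rad = np.radians(ang)
        start = (cx + r0 * np.cos(rad), cy + r0 * np.sin(rad))
        length = float(rng.uniform(2.0, 5.0))
        tid = f"b{k}"
        traces.append(straight(tid, "blind", start, ang, length))
        truth_traces.append(
            {
                "trace_id": tid, "kind": "blind", "length_um": length,
                "orientation_deg": float(min(ang % 180.0, 180.0 - ang % 180.0)),
                "diameter_um": None, "myelinating": False,
            }
        )
    cell = OligoCell(cell_id, (cx, cy), soma_diameter_um, tuple(traces))
    truth = {
        "kind": "oligo_cell",
        "counts": {
            "primary": n_primary,
            "secondary": n_secondary,
            "blind": n_blind,
            "myelinating": sum(t["myelinating"] for t in truth_traces),
        },
        "traces": truth_traces,
    }
    return cell, truth
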