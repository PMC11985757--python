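"""Independent brute-force oracles used by the tests.

These deliberately avoid the library code paths they check: ray casting
instead of shapely, Monte-Carlo rasterization instead of the shoelace
formula, a dense projection sweep instead of rotating calipers, and
exhaustive assignment instead of greedy matching.
"""

from __future__ import annotations

from itertools import permutations

import numpy as np


def ray_cast_inside(point, vertices) -> bool:
    """Even-odd ray casting point-in-polygon (boundary counts as inside)."""
    x, y = point
    n = len(vertices)
    inside = False
    for i in range(n):
        x1, y1 = vertices[i]
        x2, y2 = vertices[(i + 1) % n]
        # on-edge check via cross product and bounding interval
        cross = (x2 - x1) * (y - y1) - (y2 - y1) * (x - x1)
        if abs(cross) < 1e-12 and min(x1, x2) - 1e-12 <= x <= max(x1, x2) + 1e-12 \
                and min(y1, y2) - 1e-12 <= y <= max(y1, y2) + 1e-12:
            return True
        if (y1 > y) != (y2 > y):
            xint = x1 + (y - y1) * (x2 - x1) / (y2 - y1)
            if x < xint:
                inside = not inside
    return inside


def mc_polygon_area(vertices, n_samples: int, seed: int = 0) -> float:
    """Monte-Carlo rasterization estimate of a polygon's area."""
    rng = np.random.default_rng(seed)
    v = np.asarray(vertices, dtype=float)
    xmin, ymin = v.min(axis=0)
    xmax, ymax = v.max(axis=0)
    xs = rng.uniform(xmin, xmax, n_samples)
    ys = rng.uniform(ymin, ymax, n_samples)
    # vectorized even-odd rule
    inside = np.zeros(n_samples, dtype=bool)
    n = len(v)
    for i in range(n):
        x1, y1 = v[i]
        x2, y2 = v[(i + 1) % n]
        crosses = (y1 > ys) != (y2 > ys)
        with np.errstate(divide="ignore", invalid="ignore"):
            xint = x1 + (ys - y1) * (x2 - x1) / (y2 - y1)
        inside ^= crosses & (xs < xint)
    return inside.mean() * (xmax - xmin) * (ymax - ymin)


def feret_sweep(points, step_deg: float = 0.1, refine: bool = True):
    """(min, max) caliper width by a dense projection-angle sweep.

    The sweep runs in ``step_deg`` steps; because the width function is
    kinked at its minimum, the minimum is additionally refined by scalar
    minimization bracketed by the neighboring sweep angles (independent
    of any hull-edge reasoning).  The maximum is smooth at its optimum,
    so the raw sweep already resolves it.
    """
    from scipy.optimize import minimize_scalar

    p = np.asarray(points, dtype=float)
    angles = np.radians(np.arange(0.0, 180.0, step_deg))
    dirs = np.column_stack([np.cos(angles), np.sin(angles)])
    proj = p @ dirs.T  # (n_points, n_angles)
    widths = proj.max(axis=0) - proj.min(axis=0)
    w_min, w_max = float(widths.min()), float(widths.max())
    if refine:
        def width_at(theta):
            d = np.array([np.cos(theta), np.sin(theta)])
            q = p @ d
            return q.max() - q.min()

        k = int(np.argmin(widths))
        lo = angles[max(k - 1, 0)]
        hi = angles[min(k + 1, len(angles) - 1)]
        res = minimize_scalar(width_at, bounds=(lo, hi), method="bounded",
                              options={"xatol": 1e-12})
        w_min = min(w_min, float(res.fun))
    return w_min, w_max


def optimal_assignment_matches(a, b, tolerance: float) -> int:
    """Maximum number of one-to-one A-B pairs with distance <= tolerance,
    by exhaustive enumeration (use only for tiny scenes)."""
    a = np.asarray(a, dtype=float).reshape(-1, 2)
    b = np.asarray(b, dtype=float).reshape(-1, 2)
    if len(a) > len(b):
        a, b = b, a
    nb = len(b)
    best = 0
    for perm in permutations(range(nb), len(a)):
        d = np.hypot(*(a - b[list(perm)]).T)
        best = max(best, int((d <= tolerance).sum()))
    return best


def band_mean_bruteforce(bins: np.ndarray, axis: str, lo: float, hi: float) -> np.ndarray:
    """Per-bin-center band mean computed loop-wise from first principles."""
    centers = [2.5 + 5.0 * k for k in range(20)]
    out = []
    for i in range(20):
        vals = []
        for j in range(20):
            orth = centers[j]
            if lo <= orth <= hi:
                vals.append(bins[j, i] if axis == "medio-lateral" else bins[i, j])
        out.append(sum(vals) / len(vals))
    return np.asarray(out)


def circle_containment(cell_xy, cell_diameter, calyx_xy, sampling_diameter) -> bool:
    """A soma disc lies fully inside the sampling circle."""
    d = ((cell_xy[0] - calyx_xy[0]) ** 2 + (cell_xy[1] - calyx_xy[1]) ** 2) ** 0.5
    return d + cell_diameter / 2.0 <= sampling_diameter / 2.0
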