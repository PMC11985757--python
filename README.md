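# glioquant

Spatial quantification of oligodendrocyte development in the nuclei of the
superior olivary complex (SOC) — the auditory brainstem's binaural processing
center comprising the MNTB, MSO and LSO.

During postnatal development, oligodendrocytes (marked by the transcription
factors Olig2 and SOX10, the myelinating-stage marker S100, and myelin basic
protein MBP) redistribute within these nuclei along their presumed tonotopic
axes, accumulate near calyx of Held synapses, and expand the tissue area a
single cell's processes cover. `glioquant` turns the manual measurements
behind such a study — soma centers marked on micrographs, nucleus boundaries
drawn on VGluT1 labeling, traced cell processes — into a reproducible,
tested analysis pipeline.

## What it computes

**Normalized density maps.** For a nucleus with boundary polygon drawn per
section, each marked soma at pixel position $(x, y)$ is mapped into the
normalized frame $r_x = 100\,(x - x_\min)/(x_\max - x_\min)$ (and likewise
$r_y$), binned into a 20×20 grid of 5 % increments, and scaled by the
section's maximum bin count, so the normalized density $d_{ij} \in [0, 1]$.
Per-section grids are averaged per nucleus and age group and rendered as
gray values (darker = denser). Counts $N$, polygon areas $A$ (shoelace ×
pixel-size², in μm² and mm²) and densities $\rho = N/A$ accompany every map.

**Tonotopic profiles.** A straight-band profile averages the density map
over the central 50 % of the orthogonal axis and reports intensity at the
20 bin centers; a curved-path variant follows a control-point polyline
(e.g. the LSO's dorsomedial→ventral→dorsolateral bend, or a medial-axis
default) with a 30 %-wide transverse window. Edge regions (5–15 % vs
85–95 % of relative location) are compared across sections with the
normality-gated dispatch below. Multi-channel image line scans (per-column
means over a rectangle, medial→lateral) serve the same purpose on raw
fluorescence.

**Co-labeling and calyx proximity.** Independently marked point sets are
overlaid by greedy mutual-nearest-neighbor matching within a tolerance
(5 μm somata / 1 μm axon profiles) to yield only-A / only-B / double
fractions. Around a calyx of diameter $D_c$, the sampling circle has
diameter $D_c + 17\,\mu m$ (the mean S100-positive soma diameter) and a
cell counts as calyx-proximal iff its soma disc lies fully inside:
$\lVert c - c_{calyx}\rVert + r_{soma} \le r_{sampling}$.

**Process morphometry.** Traced processes are classed primary / secondary /
blind; per process the pipeline reports arc length, chord angle to the
medio-lateral axis folded to [0°, 90°], and the 5-point mean diameter
(width at arc-length fractions 0.1, 0.3, 0.5, 0.7, 0.9). Myelination is
verified on 5.55 μm cross-profile chips: two dominant intensity peaks
flanking a low center. Per cell, the coverage polygon is the convex hull of
all trace points with area and min/max Feret (caliper) diameters by
rotating calipers; roundness = Feret min / Feret max.

**Statistics.** Every grouped comparison passes a Shapiro–Wilk gate
(α = 0.05 per group): all normal → mean ± SEM, t-test / ANOVA with
Holm–Šídák post-hoc; otherwise median ± SEM, Mann–Whitney U /
Kruskal–Wallis with Dunn's post-hoc. p < 0.05 is significant.

Because studies of this kind rarely deposit raw micrographs, the package
ships seeded generators (`glioquant.synthetic_data`) for every input class
— gradient point patterns, banded MSO images, hollow/filled tube chips,
calyx scenes, traced cells — each with analytic ground truth, so the whole
pipeline is validated by parameter recovery.

## Worked example

Fourteen synthetic MNTB sections (150 cells each, planted 2:1
lateral:medial density gradient) analyzed end to end:

```python
import numpy as np
from glioquant import NucleusROI, SectionFrame, band_profile, edge_compare
from glioquant.density_mapping import density_record, grid_from_marks
from glioquant.synthetic_data import gen_points

roi = NucleusROI("s01", "MNTB", ((0, 0), (400, 0), (400, 250), (0, 250)))
frame = SectionFrame("s01", pixel_size_um=0.6)

profiles, records = [], []
for s in range(14):
    marks, _ = gen_points(roi, n=150, gradient_axis="x", gradient_ratio=2.0,
                          section_id=f"s{s:02d}", seed=s)
    records.append(density_record(marks, roi, frame))
    profiles.append(band_profile(grid_from_marks(marks, roi), "medio-lateral"))

dens = [r.density_per_mm2 for r in records]
print(f"cells/section: {records[0].count}, nucleus area: {records[0].area_mm2:.4f} mm^2")
print(f"density: {np.mean(dens):.0f} cells/mm^2")
cmp_ = edge_compare(profiles)
print(f"medial (5-15%) mean intensity:  {cmp_.low_mean:.3f}")
print(f"lateral (85-95%) mean intensity: {cmp_.high_mean:.3f}")
print(f"{cmp_.test_name}: p = {cmp_.p_value:.2g}")
```

prints

```
cells/section: 150, nucleus area: 0.0360 mm^2
density: 4167 cells/mm^2
medial (5-15%) mean intensity:  0.081
lateral (85-95%) mean intensity: 0.141
unpaired t-test: p = 0.0039
```

The 400×250 px boundary at 0.6 μm/px is 0.036 mm², so 150 cells give
4167 cells/mm² (fixed-n sampling: identical across sections). The planted
lateral accumulation surfaces as a higher edge-region intensity in the
normalized map (0.141 vs 0.081) and the gate chose the unpaired t-test
because both per-section edge samples passed Shapiro–Wilk.

A CLI mirrors the library (`glioquant ingest | density | profile |
linescan | colabel | calyx | stats | simulate`); see `glioquant --help`.

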