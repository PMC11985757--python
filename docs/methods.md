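# Methods

This note records the models, conventions, parameter choices and known
limitations behind `glioquant`, at the level of detail a maintainer or
reviewer needs to judge what the pipeline does and what its passing tests
do and do not demonstrate.

## Coordinate conventions

Mark tables arrive in the image frame (row 0 at top); anatomical dorsal is
up. Ingest converts exactly once into an internal anatomical frame:
`y_anat = H − y_px` when the image height `H` is known, otherwise a mirror
about the ROI bounding box. Left-hemisphere marks and ROIs are mirrored in
x so that +x = lateral everywhere, with a provenance flag (`mirrored`) so
a second pass cannot double-flip. All downstream normalization is the
plain bounding-box map to 0–100 %; the choice of the axis-aligned bounding
box (rather than per-row extremes) as the 100 % frame is a design decision:
it is reproducible, order-free, and treats the two axes symmetrically.
Marks exactly on the polygon boundary count as inside — manual marks placed
on faint boundaries should not be dropped silently.

## Density maps

The grid is fixed at 20×20 (5 % increments); configurability was rejected
so cross-section averaging is always well defined. Bins are half-open
[5k, 5k+5) with the final bin closed at 100. Normalization divides by the
section's maximum bin; an all-zero section is an error at this stage and
is excluded from map averaging (with a warning) while still contributing
count = 0 and density = 0 to the per-section records — maximum
normalization is undefined at zero, density is not. Marks inside the
bounding box but outside the polygon are excluded before binning. Bins
that a non-rectangular polygon only partially covers are *not* re-weighted
by covered area; this reproduces the plain binning procedure but
under-weights edge bins — a known, deliberate limitation. Rendering maps
density 1 → gray 0 and 0 → 255, rounded half-up, with dorsal at the top
row of the image.

## Profiles

Density-map profiles sample at bin centers (2.5, 7.5, …, 97.5 %). The
straight band spans the central 50 % of the orthogonal axis; an optional
center shift of up to ±10 % is exposed because the centering tolerance and
the band extent are two readings of the same convention — the band extent
is primary here, the shift is configuration. With center sampling, the
5–15 % edge window covers exactly the bins centered at 7.5 and 12.5 %.

The curved path is a user-supplied control-point polyline in the
normalized frame, arc-length parameterized, sampled at 20 positions with
a transverse window of half-width 15 % perpendicular to the local tangent
and half a sample spacing along it; this makes a straight path exactly
equal to a 30 %-wide band profile (verified in tests). A helper derives a
default path as the medial-axis skeleton of the ROI polygon (rasterized
preserving aspect, padded so a bbox-filling ROI still has background,
ordered by a nearest-neighbor walk); it is a reproducible stand-in for a
freehand path, not an inference of one.

Edge comparison averages each section's profile over 5–15 % and 85–95 %
and feeds the two per-section samples to the statistical dispatch. No
smoothing is applied to profiles before averaging, and intensities are
per-section max-normalized densities; both are stated choices where the
convention could be read otherwise.

Image line scans are per-column means over a rectangle whose long axis is
medio-lateral, in μm from the medial edge; left-hemisphere scans are
reversed so output is always medial→lateral (mirror equivariance is a
tested invariant).

## Myelin cross-profile detector

A myelinated axon cut transversely shows two bright walls around a dim
lumen. The detector smooths the cross-profile (Gaussian, σ = 1 sample —
the verification chips are averaged along the process axis first, so this
only suppresses single-pixel spikes), finds peaks with prominence ≥ 10 %
of the chip's dynamic range, takes the two most prominent as candidate
walls, and requires: the valley between them in the central half of the
chip, valley ≤ 0.6 × the lower wall, and walls ≥ 2.0 × the background
(median of the outer 20 % of samples per side). The ratios 0.6 / 2.0 and
the prominence fraction are config-exposed defaults fixed in tests; the
criterion itself is qualitative ("low center flanked by two peaks"), so
the numbers are this package's operationalization. An all-zero profile is
classified `False`, not an error. At SNR 5 (wall-minus-background over
noise sd) the detector measures ≥ 95 % sensitivity and specificity on 200
generated chips.

## Co-labeling

Overlay matching is greedy mutual nearest neighbor: repeatedly pair the
globally closest unmatched pair within tolerance. This is deterministic
(ties broken by index), order-independent, and equals optimal assignment
whenever somata are separated by more than twice the tolerance — which
soma-scale physiology guarantees (somata ≈ 17 μm, tolerance 5 μm). The
tolerance defaults — 5 μm for somata (about a soma radius), 1 μm for axon
cross-profiles — are prominent configuration, not constants, because the
original overlay procedure was visual. Three-channel overlays match A–B
first, then the A∩B midpoints and remaining singles against C; sequential
matching is one of several defensible rules for a procedure the source
protocol leaves unstated.

Calyx proximity: sampling-circle diameter = calyx diameter + 17 μm (the
measured mean S100 soma diameter), concentric with the calyx. A cell
counts iff its soma disc (measured diameter, or the 17 μm default with a
log entry) lies fully inside. As the soma diameter → 0 the rule converges
to center-in-circle membership (tested).

## Morphometry

Process length is polyline arc length (not straight-line extent — a
choice, flagged). Orientation is the undirected chord angle to the
medio-lateral axis folded to [0°, 90°]; the Feret angle stays in
[0°, 180°) as is conventional for shape descriptors. The 5-point diameter
reads widths at arc-length fractions 0.1 … 0.9 by linear interpolation of
width samples; positions marked unmeasurable (NaN, overlapping processes)
substitute the nearest measurable sample, and a process with no
measurable position yields a missing value. Image-based widths use the
full width at half maximum of a perpendicular intensity profile
(half-length 2.8 μm, matching the 5.55 μm chips), background taken as the
lower of the two profile-end means, crossings sub-sampled linearly.

The coverage polygon is the convex hull of all trace points — a
deterministic, conservative approximation of a manually drawn outline
around the outermost processes (a concave alpha-shape variant is out of
scope). Feret extremes use rotating-calipers facts: the maximum is
attained by a vertex pair, the minimum perpendicular to a hull edge.

## Statistical dispatch

Normality gating is per group (Shapiro–Wilk, α = 0.05, config-exposed);
"every group must pass" is the conventional reading where the protocol
does not specify pooled residuals. SEM accompanies the median as well as
the mean — statistically unusual but reproduced as the fixed reporting
convention of this pipeline's domain; `bootstrap_median_ci` is provided
as a clearly labelled alternative. The underlying tests are standard
published procedures and are called from scipy/statsmodels; the
pipeline's contribution is the gated dispatch and reporting format.
Dunn's post-hoc test is implemented here (rank z-approximation with tie
correction) because no pre-installed package provides it; pairwise
p-values are Šidák family-corrected by default (`p_adjust` accepts
`sidak | bonferroni | holm | none`), matching the
corrected-for-multiple-comparisons convention of common GUI statistics
packages. Measured over 2,000 null replicates (two normal groups,
n = 15), the full dispatch's type-I error is ≈ 5 % as designed.

## Synthetic data: what it emulates, and what it does not

Generators mirror the study's scales: nucleus bounding boxes 150–500 μm,
soma diameters ≈ 17 μm (truncated normal, sd 1.5), 5.55 μm chips, the
359 × 72 μm MSO rectangle, counts of 10–300 marks per nucleus section.
Point patterns are fixed-n by default (counts are reported per section);
a Poisson mode serves density-recovery tests. Gradients are linear in the
normalized axis with a stated lateral:medial ratio, realized by rejection
sampling. MSO images are Gaussian bands plus Gaussian noise; tube chips
are ideal walls/cores plus noise; traced cells use straight chords so
that planted length, orientation and taper are *exactly* the analytic
ground truth recorded in each generator's truth structure.

What passing recovery tests therefore show: the pipeline's geometry,
binning, matching, detection and statistics are correct against known
structure at realistic scales and noise. What they do not show: robustness
to the many properties of real micrographs the generators deliberately
omit — point-spread blur, spectral bleed-through, uneven illumination,
marking bias near faint boundaries, curved section geometry, z-projection
artifacts. Claims about real tissue require the real inputs.

## Numerical choices and degenerate inputs

- Pixel size comes from run configuration; published pixel↔μm pairs for
  the same microscope are mutually inconsistent, so no value is hard-coded.
- Self-intersecting ROI polygons, zero-extent bounding boxes, empty
  sections at normalization, collinear cells at hull construction, and
  probability vectors not summing to 1 all raise errors naming the object.
- Malformed mark rows are skipped with a logged line number; a missing
  required column is a format error (the file, not a row, is wrong).
- Grid rendering rounds half-up (`floor(x + 0.5)`) to make the 0.5 → 128
  mapping exact rather than banker's-rounded.
- Greedy matching sorts candidate pairs by (distance, index) so results
  are reproducible across runs and platforms.
- Simulation sizes in the test suite (e.g. 40-replicate versions of the
  100-replicate recovery checks, 600-replicate type-I screen) are the
  package's fast defaults; the acceptance script runs the full sizes
  (100 replicates, 2,000 null replicates, 10⁷ Monte-Carlo samples).

## Known limitations

- Edge bins of non-rectangular nuclei are under-weighted (no area
  re-scaling), as noted above.
- The convex coverage hull overestimates concave cells' territory.
- The medial-axis default path can pick up short diagonal spurs at blunt
  ROI ends; supply explicit control points for publication-grade profiles.
- The gradient-recovery power at the reference condition (ratio 2,
  14 sections × 150 marks) is ≈ 91 %, so single 100-replicate runs
  fluctuate around 90/100.
- Statistical dispatch assumes independent per-section observations;
  sections nested in animals/litters are not modelled (no mixed models).
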