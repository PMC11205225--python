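# Methods

## Density estimation

The pipeline's core primitive is an adaptive-window, Voronoi-bounded density
estimate.  Cone coordinates (pixels, origin at the ROI's top-left corner,
x rightward, y downward) are first rescaled to a common pixel pitch
(default 0.25 µm/px) so every field shares one analysis grid.  The Voronoi
tessellation of all cones is computed once per field (scipy/Qhull); a cell is
*finite* if its polygon is closed and *bounded* if, additionally, every
vertex lies inside the ROI rectangle.

At a grid point `p`, an axis-aligned square window centered on `p` grows in
whole-pixel side increments until it strictly contains (all polygon vertices
interior) at least `k = 150` Voronoi cells.  The density reported at `p` is

    density(p) = n_contained / Σ areas(contained cells)

the reciprocal mean bounded-cell area.  This convention is exact on a
hexagonal lattice — a lattice of spacing `s` has cell area `√3/2·s²`, hence
density `2/(√3·s²)` — and is unbiased for uniform mosaics regardless of the
window quantization (a count-per-window-area rule would be biased low by
roughly two cell diameters per window side, ~15% at foveal densities,
because containment erodes the effective window).

Because a convex polygon lies in an open axis-aligned box iff its bounding
box does, each cell's containment reduces to the Chebyshev-type distance
from `p` to the farthest corner of the cell's bounding box; the minimal
window is an order statistic of those distances.  A k-d tree preselects
3·k candidate cones per grid point, with a conservative certificate (an
excluded cone's cell radius is at least its center distance/√2) and an
exact full-field fallback where the certificate fails.  Correctness is
defined by an independent exhaustive window search (shapely polygon
containment at every candidate window side), which the engine matches to
well under 1% in the test suite.

### Boundary handling

Grid points whose accepted window would leave the ROI are *missing*, not
edge-corrected.  In addition, an `edge_margin_um` buffer (pipeline default
10 µm ≈ 4 lattice spacings) invalidates points whose window approaches the
ROI edge: cones near the boundary have distorted Voronoi cells (their
outside neighbors were never observed), and the margin keeps only windows
whose member cells are boundary-clean.  This makes a 300-µm ROI and the
central 300-µm of a 500-µm ROI of the same retina agree *exactly* — without
the margin, the two differ subtly in a band near the smaller ROI's edge.

## Foveal metrics

- **PCD**: maximum over valid cells; ties broken row-major (smallest row,
  then column).  Grid quantization localizes the peak to one cell.
- **80th-percentile region**: nearest-rank percentile (the
  ceil(0.8·n)-th smallest valid value; no interpolation) thresholds the
  map at ≥; its area is the cell count × cell area.
- **CDC**: density-weighted centroid of that region; its value is the
  density of the nearest valid cell (grid-consistent, never exceeds PCD).
- **PCD–CDC offset**: Euclidean distance in µm.
- **Angular units**: cones/deg² = cones/mm² × (retinal mm/deg)², with
  mm/deg from Bennett's adjusted axial-length formula
  `q = 0.01306·(AL − 1.82)`.  The conversion is isolated in one function so
  a different magnification model can be substituted.

Because the percentile threshold is a rank statistic, the contour area is
~20% of the valid analysis area by construction and is therefore only
comparable across visits measured on identical support.  All metrics are
accordingly extracted on a central 300 × 300-µm analysis crop (grid-aligned,
revalidated against the crop bounds) whenever the source ROI is larger.
Values entering the cohort table are rounded to three significant digits,
the stated uncertainty of the image scale.

## Intervisit comparison

Two visits' matrices are aligned by a whole-cell translation bringing their
CDCs into register (no rotation/scaling/interpolation; at 0.25-µm pixels the
registration error is ≤ half a grid cell).  The difference map is
visit 2 − visit 1 over the overlap, cropped to 300 × 300 µm about the common
CDC and valid only where both inputs are.  Cross-sections take the single
row/column through the CDC cell, tiled into contiguous 5-µm bins centered on
the CDC (the bin spanning [−2.5, 2.5) µm holds the CDC sample).  Composite
profiles average per-subject bin means and report the between-subject SD and
per-bin subject count.

## Agreement statistics

Differences are oriented visit 2 − visit 1 throughout.  Per metric:
percent change 100·|v2 − v1|/v1; Shapiro–Wilk on the differences (scipy's
Royston implementation; undefined — reported as NaN — when the differences
are all equal); paired t (identical pairs ⇒ t = 0, p = 1; zero variance
with nonzero mean ⇒ ±∞, p = 0); Pearson r with a Fisher-z CI
(atanh r ± z·(n−3)^−1/2); Bland–Altman bias ± 1.96·SD limits of agreement
with t-based CIs, the LoA CIs using the classical √(3/n)·SD approximation.
No multiple-testing correction is applied.  Correlations of intervisit
interval against absolute differences are reported alongside.

## Synthetic mosaics

The generator emulates foveal topography, not images: a hexagonal lattice
(random orientation) at the peak spacing is warped by an area-preserving
radial map whose Jacobian is exactly `e^{−r/a}`, so realized local density
follows `D(r) = D₀·e^{−r/a}` analytically; Gaussian jitter models lattice
disorder plus marking error.  Defaults: `D₀ = 187,000 cones/mm²`,
`a = 250 µm` (density halves by ~170 µm eccentricity, matching normal
foveal falloff), jitter SD 0.3 µm.  Cohort draws: peak density
U(150k, 220k) cones/mm², falloff U(220, 280) µm, peak decentration up to
15 µm, axial length U(22.5, 25.3) mm, intervisit interval U(2.48, 4.28)
years.  The revisit model applies a rigid offset, a multiplicative scale
error about the ROI center, extra jitter, binomial cone misses, and uniform
spurious points; its defaults are placeholders, as the real
cone-identification error process is uncharacterized.  Each subject's
visit 1 is the central 300-µm crop of a 500-µm master mosaic and visit 2 is
the perturbed master, so a zero-perturbation cohort is an exact null.

What the generator does *not* emulate: reflectance variation and detection
difficulty that correlate with cone spacing, spatially structured marking
error, anisotropic packing, and real between-visit biological change.
Passing tests therefore demonstrate correctness of the *measurement
pipeline* under a known point process, not performance of cone detection on
real images.

## Numerical choices and problem sizes

- Window growth quantum: one pixel of the common grid; acceptance of the
  smallest strictly-qualifying window makes ties impossible.
- The engine's containment test is strict (open window); knife-edge
  coincidences between a polygon vertex and a window edge have measure zero
  for jittered mosaics.
- Dense grids are exact; the validation suite samples every 8th–16th pixel
  (2–4 µm), which quantizes PCD/CDC locations but leaves values unbiased.
- Single-peak recovery tests use a falloff of 400 µm: the 150-cone window
  averages density over a ~28-µm footprint, so for steeper falloffs the
  window mean at the peak sits a few percent below the point-peak value —
  an intrinsic property of the estimator, shared by any windowed count.
- Validation problem sizes (chosen for single-CPU minutes): 19-subject
  null cohorts at full 300/500-µm ROIs with 4-µm sampling; bias-recovery
  replicates at 6 subjects and 160/240-µm ROIs; brute-force window oracle
  on ≤ 500-cone fields with k = 50.

## Known limitations

- Bounded-cell density is a harmonic-type local mean over the window; near
  sharp density gradients it reflects the window average, not the point
  value.
- Whole-cell CDC alignment leaves ≤ half-cell registration error in
  difference maps.
- The percentile convention (nearest-rank) and the common scale are
  documented defaults; other implementations may use interpolated quantiles
  or different pitches, shifting contour areas by a cell-quantization
  amount.
- Angular conversion assumes Bennett's adjusted axial-length model; eyes
  outside 20–30 mm trigger a warning.
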