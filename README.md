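# conemetrics

Quantifies the human foveal cone photoreceptor mosaic from cone coordinates
and measures how reproducible those measurements are across imaging visits.

Adaptive optics scanning light ophthalmoscopy (AOSLO) resolves individual
cones in the living retina; after cone centers are marked, each region of
interest (ROI) reduces to an x,y coordinate list with a spatial scale.
`conemetrics` takes such coordinate files and computes:

- **Density matrices** — at every sampled grid point, a square window grows
  until it contains ≥ 150 cones whose Voronoi domains lie fully inside it;
  local density is the number of contained cells divided by the sum of their
  Voronoi areas (exactly 2/(√3·s²) on a hexagonal lattice of spacing s).
- **Foveal metrics** — peak cone density (PCD, location and value), the cone
  density centroid (CDC, the density-weighted centroid of the region at or
  above the 80th percentile of density), the 80th-percentile isodensity
  contour area, and the PCD–CDC offset, in cones/mm² and — via Bennett's
  adjusted axial-length magnification, q = 0.01306·(AL − 1.82) mm/deg — in
  cones/deg².
- **Intervisit comparison** — CDC-aligned visit 2 − visit 1 difference maps
  cropped to 300 × 300 µm, with horizontal/vertical cross-sections through
  the CDC averaged in 5-µm bins and composited across subjects.
- **Cohort agreement statistics** — per-subject percent change, Shapiro–Wilk
  normality of the differences, paired t, Pearson r with a Fisher-z 95% CI,
  and Bland–Altman mean bias with 95% limits of agreement
  (bias ± 1.96·SD) and their CIs.

A synthetic mosaic generator (jittered hexagonal packing warped so local
density follows `D(r) = D₀·exp(−r/a)` exactly, plus a revisit measurement
model) provides ground truth for every stage, so the whole pipeline is
testable without any imaging data.

## Worked example

```python
import numpy as np
from conemetrics import (PipelineConfig, run_cohort)
from conemetrics.synthetic_data import RevisitParams, generate_cohort

subjects = generate_cohort(19, seed=7,
                           revisit=RevisitParams(extra_jitter_sd=0.35, seed=1))
result = run_cohort(subjects, PipelineConfig(stride=16))
t = result.tests.loc["pcd_mm2"]
a = result.agreement["pcd_mm2"]
print(f"PCD visit 1: {t.mean_v1:,.0f} ± {t.sd_v1:,.0f} cones/mm^2")
print(f"paired t = {t.t:.2f} (df = {t.df:.0f}, p = {t.p:.2f})")
print(f"bias = {a.bias:,.0f} cones/mm^2, "
      f"LoA [{a.loa_lower:,.0f}, {a.loa_upper:,.0f}]")
```

prints

```
PCD visit 1: 174,684 ± 24,425 cones/mm^2
paired t = 2.14 (df = 18, p = 0.05)
bias = 474 cones/mm^2, LoA [-1,416, 2,364]
```

Here the only revisit perturbation is 0.35-µm cone-marking jitter, so the
limits of agreement are narrow (±1900 cones/mm², ~1%) and even the tiny
positive bias jitter induces in a peak statistic (+474 cones/mm², 0.3%)
sits at the edge of detectability.  Adding realistic per-session image-scale
error (see `scripts/acceptance.py`) widens the limits of agreement to a few
percent and the bias becomes non-significant, mirroring intervisit studies
of real AOSLO data.  Metric values entering the cohort table are rounded to
three significant digits, reflecting the uncertainty of the image scale.

A thin CLI mirrors the library:
`conemetrics ingest|density|metrics|intervisit|cohort --help`.

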