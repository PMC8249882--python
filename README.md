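# cortexshift

Vertex-wise measurement of longitudinal cortical atrophy from pairs of
cortical surface reconstructions, with anatomically constrained spherical
registration, and permutation-based group inference.

## The problem

Longitudinal studies of neurodegeneration (e.g. two-year follow-up of
cognitively normal, MCI and Alzheimer's cohorts) need per-vertex maps of
how the cortex changed between two scans.  Cortical *thickness* change is
easy to measure but noisy; cortical *surface-area* change requires an
accurate within-subject correspondence between the two reconstructions —
the hard part — and *volume* change combines both.  This package
implements that measurement chain for researchers in surface-based
morphometry:

* **Registration** (`cortexshift.registration`): both timepoints carry a
  spherical parameterization; a coarse-to-fine control grid of icosphere
  vertices deforms the input sphere to minimize

  `E(φ) = mean squared feature mismatch + λ · strain energy per unit area`,

  where the strain energy of the warp is evaluated on the **anatomical**
  surface (the defining idea of anatomically constrained surface
  matching).  Per face, with principal stretches λ₁, λ₂ of the in-plane
  affine map, the density is

  `W = c_shear (R/2 − 1) + c_bulk (J + 1/J − 2)`, `R = λ₁/λ₂ + λ₂/λ₁`, `J = λ₁λ₂`.

  Registration is run in both directions and the two implied area-change
  maps are averaged to cancel directional bias.

* **Morphometry** (`cortexshift.morphometry`): per vertex,
  `ΔCT = log2(CT₂/CT₁)` (timepoint maps smoothed with a 20 mm FWHM
  geodesic Gaussian), `ΔSA = log2(SA₂/SA₁)` with each vertex owning one
  third of every incident triangle's area, and
  `ΔV = log2((SA₂·CT₂)/(SA₁·CT₁)) = ΔCT + ΔSA` exactly.  Global percent
  losses, within-subject variances and ROI tables (icosahedron-face
  parcels with a designated medial wall) follow the same formulas.

* **Inference** (`cortexshift.stats`): one-sample t, two-sample t and
  one-way F maps, threshold-free cluster enhancement
  (`TFCE(v) = Σ_h e(h,v)^E h^H dh`, extent = component vertex-area), and
  family-wise error control through the permutation distribution of the
  maximum TFCE statistic (sign-flips for one-sample tests, label
  permutations for group tests).  Global ANOVA + Tukey HSD + Cohen's d and
  ROI MANOVA (Pillai's trace) + Bonferroni pairwise tests round out the
  group analyses.

* **Synthetic ground truth** (`cortexshift.synth`): folded pseudocortices
  with known, exactly measured atrophy; per-scan correlated noise standing
  in for 3.0 T vs 1.5 T image quality; and regridded follow-up surfaces so
  that registration is exercised realistically.  The robustness
  experiments of `cortexshift.experiments` use it to study cross-noise
  consistency and detection power versus sample size (12–90 subjects per
  group).

## Worked example

```python
import numpy as np
from cortexshift import (NoiseSpec, generate_cohort, register_bidirectional)

sub = generate_cohort(2, {"AD": 1.0}, NoiseSpec.preset("3T"), level=4, seed=2)[0]
res = register_bidirectional(sub)
cortex = ~sub.baseline_wall.values
rec, tru = res.area_change.values[cortex], sub.truth_area[cortex]
patch = tru < -0.02
print(f"in-patch mean log2 area change: recovered {np.nanmean(rec[patch]):+.4f} "
      f"(truth {tru[patch].mean():+.4f})")
print(f"per-vertex MAE vs truth {np.nanmean(np.abs(rec - tru)):.4f} log2 units")
```

prints (seed 2):

```
in-patch mean log2 area change: recovered -0.0349 (truth -0.0352)
per-vertex MAE vs truth 0.0202 log2 units
```

i.e. inside this AD-analog subject's atrophy patches the registration
recovers the true mean area loss (−0.035 log2 ≈ 2.4% over the simulated
two years) almost exactly, with a per-vertex error of about 1.4% local
area.  The scripts in `examples/` walk through each stage
(simulation, registration, change maps, group inference, robustness
experiments) the same way; a thin CLI (`cortexshift simulate|register|
stats|experiment`) wraps the same functions for shell use.

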