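"""Register one subject's two timepoints and check recovery of true change.

Anatomically constrained spherical registration aligns the two surfaces;
the warp implies a per-vertex log2 surface-area change, which is compared
against the generator's exact ground truth.
"""

import numpy as np

from cortexshift import NoiseSpec, generate_cohort, register_bidirectional

sub = generate_cohort(2, {"AD": 1.0}, NoiseSpec.preset("3T"), level=4, seed=2)[0]
res = register_bidirectional(sub)

cortex = ~sub.baseline_wall.values
rec = res.area_change.values[cortex]
tru = sub.truth_area[cortex]
print(f"subject {sub.subject_id}: registration {'failed' if res.failed else 'converged'}")
for direction in ("forward", "reverse"):
    trace = res.diagnostics[direction]["objective"]
    print(f"  {direction}: objective per level "
          + " -> ".join(f"{t[-1]:.5f}" for t in trace))
patch = tru < -0.02
print(f"  in-patch mean log2 area change: recovered {np.nanmean(rec[patch]):+.4f} "
      f"(truth {tru[patch].mean():+.4f})")
print(f"  per-vertex MAE vs truth {np.nanmean(np.abs(rec - tru)):.4f} log2 units")
print("\nAn MAE of ~0.02 log2 units corresponds to ~1.4% local area error;")
print("inside the atrophy patches the recovered mean tracks the true loss.")
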