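"""Segment a phantom tumor with the fuzzy-MRF model and score it.

Shows the fitted density parameters, the optimization trace, and the Dice
overlap of the resulting gross tumor volume (GTV) with ground truth.
"""

import numpy as np

import fuzzymrf as fm

ct, suv, truth = fm.generate_phantom(fm.default_spec(seed=0))
result = fm.segment(ct, suv, fm.OptimConfig(), mode="petct")

p = result.params
print("fitted densities:")
print(f"  normal SUV  ~ N({p.mu10:.3f}, {p.sigma10:.3f}^2)")
print(f"  normal CT   ~ N({p.mu20:.1f}, {p.sigma20:.1f}^2)")
print(f"  tumor  CT   ~ N({p.mu21:.1f}, {p.sigma21:.1f}^2)")
print(f"  tumor  SUV  ~ U[a={p.a:.3f}, b={p.b:.3f}] (density 1/(b-a) above a)")

tr = result.trace
print(f"\noptimizer: {tr.n_iter} iterations, converged={tr.converged}, "
      f"energy {tr.energy[0]:.1f} -> {tr.energy[-1]:.1f} (monotone: "
      f"{bool((np.diff(tr.energy) >= 0).all())})")

gtv = int(result.mask.data.sum())
print(f"\nGTV: {gtv} voxels ({gtv * np.prod(result.mask.spacing):.0f} mm^3), "
      f"truth {int(truth.data.sum())} voxels")
print(f"DSC vs ground truth: {fm.dsc(result.mask, truth):.4f}")
print("\nA DSC near 1 means the min/max PET/CT fusion recovered the tumor "
      "while rejecting the CT-identical chest-wall slab.")
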