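# fuzzymrf

Fuzzy Markov random field (MRF) segmentation of lung tumors on co-registered
PET/CT volumes.

## The problem

Lung tumors that abut the chest wall or mediastinum are hard to delineate on
CT: the adjacent soft tissue has nearly the same intensity. PET separates
them — tumor standardized uptake values (SUV) are elevated — but PET's
spatial resolution is coarse, so PET-only contours over-reach. Radiotherapy
planning needs a gross tumor volume (GTV) that uses both channels. This
package implements a fuzzy-MRF segmentation that fuses the two modalities
through a min/max joint likelihood, together with a synthetic phantom
generator and Dice-based evaluation so the whole pipeline runs and is tested
without clinical data.

It is aimed at medical-image-analysis researchers: the primary interface is
the Python API (see `examples/`), with a thin `fuzzymrf` CLI
(`phantom` / `segment` / `evaluate`) for shell use.

## The model

Each ROI voxel *i* carries a membership degree *x<sub>i</sub>* ∈ [0, 1] to
the tumor class, estimated by maximizing

C(**x**) = Σ<sub>i</sub> { ln[ x<sub>i</sub> min(p₁₁(y<sub>i,SUV</sub>), p₂₁(y<sub>i,CT</sub>)) + (1 − x<sub>i</sub>) max(p₁₀(y<sub>i,SUV</sub>), p₂₀(y<sub>i,CT</sub>)) ] − β Σ<sub>j∈R<sub>i</sub></sub> (x<sub>i</sub> − x<sub>j</sub>)² }

where p₂₀/p₂₁ are Gaussian CT densities of normal/tumor tissue, p₁₀ is the
Gaussian SUV density of normal tissue, and p₁₁ is uniform — 0 below an SUV
threshold *a*, 1/(b−a) at or above it, with *b* the ROI's SUV maximum. The
min demands that a voxel look like tumor on *both* modalities; the max lets
it look normal on either. R<sub>i</sub> is a 5×5×3 neighborhood and β weighs
the Gibbs smoothness prior. Parameters are fitted by moment matching over
rough regions obtained by thresholding per-modality fuzzy C-means membership
maps at 0.1; C(**x**) is maximized by projected gradient ascent and the
converged field is thresholded at 0.5 into the binary GTV. Quality is
quantified with Dice's similarity coefficient, DSC = 2|v₁∩v₂|/(|v₁|+|v₂|).

## Worked example

```sh
python examples/segment_phantom.py
```

prints (seed 0):

```
fitted densities:
  normal SUV  ~ N(1.008, 0.096^2)
  normal CT   ~ N(-699.8, 29.9^2)
  tumor  CT   ~ N(40.0, 29.8^2)
  tumor  SUV  ~ U[a=1.922, b=6.007] (density 1/(b-a) above a)

optimizer: 158 iterations, converged=True, energy 22305.5 -> 22485.0 (monotone: True)

GTV: 770 voxels (2310 mm^3), truth 771 voxels
DSC vs ground truth: 0.9994
```

The phantom's tumor and chest-wall slab share a CT mean (~40) over lung
background (~−700), so the CT Gaussians alone cannot separate them; the
fitted tumor-SUV uniform (threshold a ≈ 1.9) carries that distinction, and
the fused model recovers 770 of the 771 true tumor voxels. The same phantom
segmented from PET alone over-segments (DSC ≈ 0.90, larger GTV), mirroring
the coarser PET resolution; `examples/compare_modes.py` shows the
mode-by-mode comparison and `fuzzymrf evaluate` the batch version.

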