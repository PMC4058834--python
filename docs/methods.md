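# Methods

## Model

Segmentation is posed as maximum-a-posteriori estimation of a fuzzy tumor
membership field **x** on a user-selected rectangular ROI of two
co-registered volumes: CT intensity y_CT and PET-derived SUV y_SUV. The
objective is

    C(x) = sum_i { ln[ x_i * A_i + (1 - x_i) * B_i ]
                   - beta * sum_{j in R_i} (x_i - x_j)^2 }

with per-voxel tumor evidence `A_i = min(p11(y_SUV), p21(y_CT))` and normal
evidence `B_i = max(p10(y_SUV), p20(y_CT))`. The min/max fusion encodes an
asymmetric clinical prior: a voxel must present tumor features on *both*
modalities to count as tumor, but normal appearance on *either* suffices to
count as normal. This is what lets the model reject chest-wall/mediastinum
voxels whose CT matches tumor (their SUV evidence vanishes) and lung voxels
whose blurred SUV is elevated (their CT evidence vanishes).

Density forms: p20, p21 Gaussian in CT; p10 Gaussian in SUV; p11 uniform —
zero below the SUV threshold `a`, height `1/(b-a)` for every value >= a
(deliberately not truncated above `b`; `b` only sets the height). The Gibbs
prior runs over a 5x5x3 window (half-extents (2,2,1): 5x5 in the finer
axial plane, 3 across slices), center excluded, truncated at ROI borders.

Assumptions: the two volumes already share one grid (registration/fusion is
upstream; `check_same_grid` enforces it, nothing is resampled); K = 2
classes within the ROI, which is chosen small enough to contain essentially
lung background plus tumor-like soft tissue.

## Parameter estimation

Fuzzy C-means (k = 2, fuzzifier m = 2, tol 1e-5, centers initialized at
evenly spaced quantiles with seeded jitter) is run separately on the ROI's
CT values and SUV values. Membership to the higher-center cluster,
thresholded strictly above 0.1, gives one rough tumor mask per modality.
Then, by moment matching (sample mean / n-1 SD — the bin-free equivalent of
fitting the region histogram for Gaussian families):

* mu21/sigma21 from CT over the CT rough foreground,
* mu20/sigma20 from CT over the CT rough background,
* mu10/sigma10 from SUV over the SUV rough background,
* `a` = minimum SUV over the SUV rough foreground, clamped from below to
  mu10 + 2*sigma10 against rough-segmentation leakage,
* `b` = maximum SUV of the whole ROI.

Degenerate regions (< 2 voxels, zero variance) raise named errors. One
additional plausibility check is ours: the SUV rough foreground's mean must
exceed mu10 + 6*sigma10. When an ROI contains no tumor at all, clustering
simply bisects the normal SUV distribution, and truncated-normal geometry
puts the upper part's mean about 4 background-SDs above the background mean
regardless of ROI size; genuine elevated uptake lands an order of magnitude
higher. The 6-SD rule separates those regimes and turns "the ROI holds no
tumor-like uptake" into an explicit error instead of a silent segmentation
of noise.

## Optimization

Projected gradient ascent: `x <- clip(x - alpha * dx, 0, 1)` with

    dx_i = -(A_i - B_i) / max(x_i A_i + (1-x_i) B_i, log_floor)
           + 4*beta * sum_{j in R_i} (x_i - x_j),

stopping when the 2-norm of the realized post-projection change is <=
epsilon. The 4*beta factor is the complete partial derivative: each pairwise
difference appears in both members' energy terms and the window is
symmetric, including at truncated borders. Clipping is our feasibility
choice; the stopping rule is evaluated on the post-projection change. The
neighbor sums are computed with separable box filters (three 1-D
correlations), so one iteration is O(N).

Numerical choices:

* `log_floor = 1e-12` inside the logarithm and the gradient denominator
  guards voxels where both densities underflow; the densities themselves are
  exact.
* `epsilon = 1e-4 * sqrt(N)` by default — scale-aware, so the per-voxel
  convergence demand is ROI-size independent. `max_iter = 5000`.
* Initialization defaults to the evidence ratio `x0 = A/(A+B)` (0.5 where
  both vanish), which starts near the data-term optimum; a flat 0.5 start is
  available.
* Monotone-ascent safeguard: if a step would decrease C, alpha is halved
  with a warning and the step retried; if no representable step increases C
  the field is stationary to machine precision and iteration stops. The
  recorded energy trace is therefore non-decreasing. At the default
  alpha = 1e-3 the safeguard never fires on the default phantom.
* `alpha = 1e-3`. For the smoothing weight we use `beta = 0.025`, chosen by
  a force-balance argument rather than tuning: with B << A the data term
  pulls a tumor voxel up with force ~1/x, while the 74-neighbor window pulls
  it toward its neighborhood mean with force 4*beta*sum(x_i - x_j). An
  isolated spurious-evidence voxel (all neighbors ~0) equilibrates at
  x* = 1/sqrt(296*beta) and is pinned below the 0.5 decision threshold only
  for beta > ~0.014; a voxel on a flat tumor boundary (half the window
  outside) stays above 0.5 only for beta < ~0.04. 0.025 is the midpoint of
  that admissible band: large enough that the MRF suppresses isolated
  false positives, small enough not to erode the tumor rim.
* Final threshold t = 0.5, the canonical fuzzy decision boundary. All knobs
  live in `OptimConfig` and are recorded in every CLI manifest.

The objective is concave wherever the mixture stays above `log_floor`
(log of an affine function minus a convex quadratic), so on well-scaled
evidence fields projected ascent attains the global maximum; the test suite
checks this against an exhaustive coordinate-wise grid search on small
instances, and checks the analytic gradient against central finite
differences.

## Synthetic phantom

`default_spec()` builds a 48x48x12 grid (1x1x3 mm): an 8x8x3-semiaxis tumor
ellipsoid in lung parenchyma, face-adjacent to a soft-tissue slab occupying
one side of the grid. Class statistics: lung CT ~ N(-700, 30^2), tumor and
confounder CT ~ N(40, 30^2) (identical means — the similar-intensity
condition is enforced as a spec invariant, within 0.5 pooled SD), normal
SUV ~ N(1.0, 0.3^2), tumor SUV ~ U(2.5, 8.0) with the lower bound 5 normal
SDs above normal uptake. The SUV channel is then convolved with a Gaussian
point-spread kernel of sigma (1, 1, 0.5) voxels, emulating PET's coarser
resolution; this is what makes PET-only segmentation genuinely over-reach
(a rim of normal voxels inherits above-threshold uptake) while the joint
model rejects that rim on the lung side through its CT term. The
ground-truth mask is the exact geometric ellipsoid, unaffected by noise or
blur. `model_consistent_spec()` disables the blur, making every SUV voxel
an independent draw from the model's own class-conditional densities — the
configuration used to validate parameter recovery, where estimator means
land within ~3 standard errors of the generating values.

What the phantom does *not* emulate: respiratory motion, scanner-specific
PSFs, CT partial-volume effects, heterogeneous (e.g. necrotic) tumor uptake,
or anatomy beyond the three-class geometry; CT units are HU-like but
uncalibrated. Passing phantom tests therefore demonstrates correctness of
the estimator and optimizer under the model's own assumptions plus a PET
resolution mismatch — not clinical accuracy, which would require fused
patient data and expert reference contours. Accordingly the evaluation
module always labels its reference as "phantom ground-truth mask (stand-in
for manual contours)".

## Evaluation

`evaluate_batch` generates phantom replicate i with seed `base_seed + i` and
scores up to three modes against truth: `petct` (full model), `pet_only`
(A = p11, B = p10; CT dropped from the min/max), and `fcm_only` (SUV
fuzzy C-means membership thresholded at 0.5, no MRF stage). DSC is computed
per volume; summaries report mean and n-1 SD; failed cases are recorded
with their error, never dropped. Default problem sizes — 20 replicates in
the acceptance script, 48x48x12 grids — keep a full batch under a minute
while leaving >500 voxels per class for stable statistics.

## Conventions and limitations

Voxel indexing is 0-based; ROI boxes are half-open on the upper corner.
Masks are written as uint8 NIfTI, other volumes as float64; affine metadata
beyond spacing is passed through uninterpreted. Known limitations: K = 2
only, single uniform uptake class (no multifocal thresholds), no automatic
ROI detection, gradient ascent only (no graph-cut/ICM solvers), and the `a`
selection rule (clamped foreground minimum) is a documented default the
user can override by supplying `ModelParams` directly to
`likelihood_fields`.
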