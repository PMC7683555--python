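# Methods

`hbpqa` classifies masked 3D hepatobiliary-phase (HBP) liver MR volumes as
*adequate* (vessels hypointense to a bright, contrast-retaining parenchyma)
or *suboptimal* (vessels near-isointense, impaired uptake).  The pipeline is
deliberately interpretable: three small families of handcrafted features
feed a random forest, and every stage is exposed as a library function.

## Preprocessing

Inputs are a scalar intensity grid `I(x, y, z)` with an aligned binary liver
mask.  The chain, in order:

1. **Mask multiplication** — intensities outside the mask are zeroed.
2. **Middle-slice selection** (`n_slices=10`) — the 10 slices along the
   third index centered on the mask's slice-axis centroid (ties toward the
   lower index, window clamped to the mask's slice range).  Rejected if
   fewer than 10 slices carry mask.
3. **Bias correction** (`bias_order=2`) — a polynomial in (x, y, z) is fit
   to log-intensity over the mask by least squares and divided out,
   preserving the in-mask geometric mean.  The fit is robustified by up to
   3 rounds of MAD trimming (|residual − median| ≤ 2.5·1.4826·MAD): dark
   vessels are structural negative outliers in log-intensity, and an
   untrimmed fit warps the field estimate around them, manufacturing a
   spurious bright tail when the field is divided out.  This is a simple
   stand-in for full B-spline N4-style correction, which is out of scope;
   it removes smooth low-order inhomogeneity, not high-order shading.
4. **Gaussian smoothing** (`sigma_vox=1.0`) — isotropic kernel.  By default
   the convolution is mask-normalized (normalized convolution): in-mask
   voxels average only over in-mask neighbours, so the zero background
   cannot darken the boundary.  Plain convolution is available
   (`mask_normalized_smoothing=False`).
5. **Mask erosion** (`erosion_radius=1`) — 6-connected (face-adjacent)
   erosion, applied once, discarding the boundary shell the smoothing
   kernel touched; rejected if the mask empties.
6. **Standardization** — in-mask mean 0, sd 1 with the population (divide
   by N) convention; out-of-mask voxels become NaN so they cannot leak into
   any downstream statistic.  The population convention makes the mixture
   moment identities below exact at the EM fixed point.

The smoothing sigma, erosion radius and mask-normalization are knobs with
no canonical values; the defaults above are recorded in each volume's
provenance log.

## Intensity features: two-component Gaussian mixture

Standardized in-mask intensities are modeled as
`(1 − π)·N(μ1, σ1²) + π·N(μ2, σ2²)` with the convention μ1 ≤ μ2: component
1 is the darker blood-vessel class, component 2 the brighter parenchyma,
and π is the parenchyma weight.  Fitting is plain EM:

- **E-step** in log-space (`logsumexp`), so posteriors are finite even
  where both densities underflow.
- **M-step** with weighted means/variances and π; component variances are
  floored at `(1e-4 · sd(x))²` because on discrete samples (e.g. a
  noiseless two-intensity phantom) the maximum-likelihood degeneracy is an
  exact zero variance.
- **Initialization** is deterministic: component means at the 25th/75th
  in-mask percentiles, equal sigmas (the sample sd), π = 0.5.
- **Convergence**: relative log-likelihood change below `tol=1e-6`
  (`max_iter=500`).  A collapsing component (σ < 1e-6) or a converged
  symmetric fixed point (μ1 = μ2 — stationary under EM but never a useful
  fit) triggers a deterministic perturbed restart, at most 5 times.

Because the sample is standardized, the parameters satisfy
`(1 − π)μ1 + πμ2 = 0` and `(1 − π)(σ1² + μ1²) + π(σ2² + μ2²) = 1`.  The
identities are *checked*, never enforced: they are consequences of
standardization and hold exactly at any EM fixed point of an exactly
standardized sample.  They make (μ2, σ2) redundant, so the intensity
features are the triple **(μ1, σ1, π)**.

## Topological features: Euler characteristic curves + FPCA

For thresholds u on a fixed grid (default 101 equispaced values on
[−3, 3] in standardized units), the excursion set `A_u = {s : I(s) > u}`
(strict inequality) is a binary grid.  Its Euler characteristic is computed
on the cubical complex whose 3-cells are the foreground voxels with all
their faces, edges and vertices: χ = V − E + F − C, the alternating sum of
cell counts, equal to components − handles + voids for well-behaved solids.
Cell counts come from logical-OR pooling of the voxel grid over incident
unit offsets, which is exact and fast; the test suite checks it against an
independent brute-force cell-enumeration oracle.  Full-3D complexes are the
default; a slice-wise 2D option exists for very large stacks.

χ(A_u) is normalized by the liver voxel count (masks differ in size),
giving a piecewise-constant curve.  Curves are smoothed into continuous
functions by right-to-left integration, `S(u) = ∫_u^{u_max} χ_norm(v) dv`,
using exact rectangle integration with the left-point step convention
(value on [u_j, u_{j+1}) is χ_norm(u_j)), so S(u_max) = 0.

Smoothed curves on the common grid are reduced by functional PCA: the
sample covariance (ddof 1) is discretized with trapezoid quadrature
weights W, the symmetrized matrix `W^{1/2} G W^{1/2}` is
eigendecomposed, eigenfunctions are normalized to unit quadrature norm and
signed so ∫φ_k du ≥ 0 (tie: first nonzero coordinate positive).  Scores
are quadrature inner products `ξ_k = ∫ (X − μ̄) φ_k du`.  The first three
scores are the topological features; on the synthetic cohorts three
components explain essentially all curve variance.  The FPCA basis is a
population object and is always fit on **training** curves only; test
curves are scored against the training basis, so no test information leaks
into the features.

## Texture features: GLCM Haralick statistics

In-mask intensities are quantized to `N_g=32` equal-width levels over the
in-mask range (the maximum maps to level N_g).  Pairs of in-mask voxels at
offset distance `d=1` along the 13 unique 3D directions are pooled into one
symmetric matrix of relative frequencies P (both orderings counted).  Four
statistics are read off: energy Σ P², entropy −Σ P ln P (natural log,
0·ln 0 ≡ 0), inverse difference moment Σ P/(1 + |k−l|²), and correlation
`(Σ k·l·P − μ_k μ_l) / (σ_k σ_l)` where σ are the square roots of the
marginal second central moments, making the statistic a Pearson correlation
bounded by 1.  A constant region has zero marginal variance; correlation is
then reported as an explicit undefined-feature object, never NaN-by-
accident.  N_g, d, and the direction set are configuration knobs; per-
direction averaging instead of count pooling is a one-line change in the
caller.

## Classification and evaluation protocol

The 10 features (3 mixture + 3 FPC + 4 texture; an external feature block
can be appended to the table) feed a random forest.  Hyperparameters — the
number of split variables (`max_features`) and trees — are tuned by mean
out-of-fold AUC over stratified 10-fold cross-validation; ties prefer
fewer split variables, then fewer trees; the winner is refit on the full
training set.  The default grid is mtry 1..min(10, p) × {250, 500, 1000}
trees.  Scores are suboptimal-class vote fractions.

Evaluation on a subject-level stratified 70/30 split reports:

- **AUC** — Mann-Whitney concordance (ties ½).
- **Specificity at 95% sensitivity** — suboptimal is the positive class;
  the highest threshold whose sensitivity reaches 0.95 is chosen
  (maximizing specificity subject to the constraint).  The high target
  reflects the clinical asymmetry: missing a suboptimal exam may end an
  acquisition before the liver has taken up contrast.
- **Percentile bootstrap CIs** (B=2000 by default) over resamples of the
  test rows; resamples missing a class are redrawn.
- **Mean Decrease Gini** importance per feature with ranks (normalized
  mean decrease in impurity as computed by the forest).

The learning-curve experiment subsamples the training rows (class-
proportional, without replacement) at a series of sizes, refits the FPCA
basis on each subsample's curves, re-tunes the forest, and evaluates every
run on the same fixed test split.

## Synthetic phantoms

No patient data ship with the package, so a phantom generator provides the
study conditions.  Each phantom is a voxelized ellipsoid (default grid
40×40×14, semi-axes 15×13×6 ≈ 4 900 liver voxels) with parenchyma
intensity 1.0, carved by `n_vessels=6` random-walk tubes (3–6 jittered
steps, dilated by a ball of radius 2–3 voxels) at intensity
`1 − contrast`; a multiplicative bias field `exp(a·cosx·cosy·cosz)` with
random phases (`bias_amplitude=0.1`) and additive Gaussian noise
(`noise_sd=0.05`) act inside the mask only.  Noise is magnitude-style
(absolute value), as MR magnitude data are nonnegative — this also keeps
the log-domain bias correction well-defined.  Everything outside the mask
is exactly zero, and a given spec (including its seed) yields a
bit-identical volume.

Cohort defaults: adequate contrast 0.8, suboptimal contrast 0.02, both
jittered ±20% per subject.  The suboptimal value is deliberately at the
noise scale: standardization removes any global intensity scale, so the
only way vessels can be "isointense" in a standardized volume is for their
contrast to drown in the noise/texture floor.  Random-walk tubes were
chosen over anatomical trees because they cheaply create handles and
components — the topology the Euler curves measure.

What the phantom does **not** emulate: anatomy (lobes, ligaments, real
vascular trees), lesions, MR physics (Rician noise statistics beyond the
magnitude clamp, slice profiles, motion), inter-scanner variation, or
segmentation error in the mask.  A pipeline that separates these phantoms
has been shown to respond correctly to the contrast phenomenology that
defines HBP adequacy — not to handle clinical variability.

## Problem sizes and numerical choices

- End-to-end verification uses a 150-phantom cohort (100 adequate / 50
  suboptimal, near the 3:1 clinical prevalence), one deterministic feature
  extraction, and 10 split/classifier seeds; contrast-gap monotonicity is
  checked at adequate-contrast levels {0.8, 0.25, 0.02} on 100-phantom
  cohorts.  The learning-curve experiment uses a 600-phantom cohort
  (400/200) with training sizes {50, 100, 200, 400} and 3 seeds.  These
  experiments use a reduced tuning grid (mtry {2, 3, 6} × 250 trees plus
  mtry 3 × 500); the library default remains the full grid.
- Thresholds at [−3, 3]: standardized in-mask intensities rarely leave
  this range; χ_norm is 0 above the in-mask maximum and χ(mask)/N below
  the minimum by construction.
- Degenerate inputs are rejected loudly rather than patched: constant
  in-mask images (standardization, quantization), masks that erode to
  empty, samples under 10 points (EM), fewer curves than components + 1
  (FPCA), single-class label vectors (all metrics).

## Known limitations

- The bias stand-in only removes low-order polynomial fields in log
  space; strong high-frequency inhomogeneity is out of reach.
- EM on heavily partial-volumed histograms (thin vessels + strong
  smoothing) has multiple local optima; the deterministic quantile init
  makes results reproducible but not globally optimal.
- The Euler characteristic is computed per threshold independently
  (O(grid × thresholds)); an incremental filtration update would be faster
  on large volumes.
- Bootstrap CIs are percentile, not BCa; at small test sizes they can
  undercover slightly.
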