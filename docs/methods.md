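# Methods

## Model

Stimuli vary along two discrete dimensions, a target A (levels
`i = 1..L_A`) and an irrelevant B (levels `j = 1..L_B`); the default design
is 2×2, matching the factorial experiments the toolkit emulates (e.g. two
face identities × two expressions). Conditions are ordered row-major over
`(i, j)`; this ordering is fixed and used for every matrix column layout and
serialization.

Encoding is a bank of N tuned channels with multivariate Gaussian trial
noise: `r | A_iB_j ~ N(f(A_iB_j), Σ(A_iB_j))`. The canonical tuning bank is
Gaussian (bell-shaped) over a user-declared real coordinate per level —
the latent dimension has no intrinsic units, so level coordinates are
declared by the user (defaults: levels at 1 and 2, channel centers tiling
[0.5, 2.5]). Sigmoidal or arbitrary banks enter as explicit tuning
matrices. Channel noise is Gaussian only; Poisson or multiplicative noise is
out of scope. Separability checks on model objects are analytic with an
absolute tolerance of 1e−10 (models are exact objects, not estimates).

Decoding is affine, `Â = β + bᵀr`, giving the closed form
`Â | A_iB_j ~ N(β + bᵀf, bᵀΣb)`. The fitted classifier is a soft-margin
linear SVM (C = 1 by default, deterministic solver settings; separable
training sets are fit exactly). Its weights are rescaled to a unit-norm
hyperplane normal so decoded values are signed distances to the boundary;
the permutation standardization is scale-free, so this choice is cosmetic
but pinned for reproducibility. The classifier is always trained pooling
both levels of the irrelevant dimension, and decoded values are taken from
that all-data classifier rather than from per-fold refits; cross-validated
projection is a documented alternative the toolkit does not implement.

Measurement is linear with additive Gaussian error, `a = Br + e`,
`e ~ N(0, Σ_e)`, stimulus-independent by assumption (a hook exists for a
user-supplied nonlinearity, without guarantees). Under this model a decoded
value from measurements is the channel-level decoded value plus independent
Gaussian noise of variance `bᵀΣ_e b`, so decoding distributions — and
difference functions between them — observed through measurements are the
clean ones convolved with that kernel. The predicted convolution is computed
by direct discrete convolution on the evaluation grid (zero padding, kernel
truncated at ±6 SD); grids are small enough that FFTs buy nothing and edge
behavior stays explicit.

## The DDS test

Decoded values from the four cells of the 2×2 design are compared with
kernel density estimates on a fixed grid: 1,000 evenly spaced points from
the pooled minimum minus half the pooled range to the pooled maximum plus
half the pooled range. The grid is built once from all four conditions
pooled and reused across permutations, guaranteeing a common support. The
raw statistic sums `|p̂_i1 − p̂_i2|` over both target levels and all grid
points *without* a grid-spacing factor, preserving the statistic's original
printed form; `l1_distance` supplies the properly scaled L1 distance
separately. The permutation standardization makes the raw scale irrelevant.

KDEs are Gaussian with Scott's rule (`h = sd · n^(−1/5)`, sample SD with one
delta degree of freedom — identical to the common automatic-bandwidth
univariate implementation). For the permutation test the default assigns
**one bandwidth per target level, computed from that level's pooled sample**
(with the per-condition sample size in Scott's factor; unbalanced designs
use the average condition size). The pooled bandwidth is invariant under
label shuffles, which makes the permutation null exactly exchangeable, and
it makes the KDE linear in sample membership, so all 200 shuffled statistics
reduce to one contrast-matrix product against a precomputed kernel matrix —
roughly 30× faster than re-evaluating kernels per shuffle, which is what
makes whole-volume searchlights practical on one core. The
`bandwidth="per-condition"` option instead recomputes each pseudo-condition's
own Scott bandwidth inside every permutation, mirroring fully automatic
per-sample bandwidth selection; both modes are tested and agree on strong
effects, and the observed statistic is always computed with the same
bandwidth rule as its null.

Standardization: labels of the irrelevant dimension are shuffled 200 times,
separately within each target level; the observed DDS's mid-rank percentile
in the resulting EDF (ties get half weight) gives two reported scales —
percentile − 50 (null ≈ 0; map reporting) and proportion (null ≈ 0.5;
region reporting). Whether the observed value joins its own EDF is
configurable (`include_observed_in_edf`, off by default). A third,
continuous companion is also computed: the z-score of the observed DDS in
the same EDF. The percentile index saturates at ±50 once the observed value
clears the whole EDF — and under the null about 1 center in 201 saturates by
chance — so map peak localization (`SearchlightMap.peak`) breaks saturation
ties with the z companion; reported map values remain on the percentile or
proportion scale.

## Competing operational tests

- **Classification accuracy**: with closed-form decoding distributions and
  a partition of the decoded axis into label regions, the accuracy table
  `P(ℓ_i | A_iB_j)` is exact Gaussian mass. *Invariance* (equal accuracy
  across B, tolerance 1e−9 on analytic tables) implies *generalization*
  (above-chance at one level implies above-chance at all); the one-way
  implication is property-tested over randomized models.
- **Weight orthogonality**: cosine of the angle between two classifiers'
  weight vectors, with the Pearson correlation of the raw vectors reported
  alongside (equal to the cosine only after mean-centering). Preserved by
  rotations, destroyed by generic linear maps — which is exactly why
  orthogonality observed in a transformed measurement space says little
  about the encoding space.
- **Pattern difference invariance**: the interaction contrast of condition
  mean patterns, `[ā(A₁B₁) − ā(A₂B₁)] − [ā(A₁B₂) − ā(A₂B₂)]`; its Euclidean
  norm is tested by shuffling B labels within A levels (p-value with the
  +1 correction, so p ∈ (0, 1]).

## Searchlight and group inference

Spheres use Euclidean distance in voxel units, radius inclusive (radius 3 →
123 offsets), anisotropy ignored. Voxel features are z-scored by column over
all trials before analysis (run-wise standardization is the flagged
alternative; the toolkit has no run structure by default). Centers whose
sphere holds fewer than two in-mask voxels, or whose decoded values
degenerate (zero spread), are missing and excluded downstream. Per-center
shuffle seeds are spawned deterministically from the top-level seed in scan
order, so maps are bit-reproducible and translation-equivariant.

Group inference is a voxelwise one-sample t on subject maps with a
sign-flip permutation null and max-statistic family-wise correction, with
exhaustive enumeration whenever `2^S` fits in the permutation budget
(identity pattern included, so the smallest attainable exhaustive p is
`2^−S`). This preserves the nonparametric logic of randomization-based
neuroimaging inference while staying fully verifiable; cluster-mass
correction, variance smoothing and TFCE are deliberately out of scope, and
`cluster_forming_threshold` exposes only the Student-t height threshold
convention. A `differential_contrast` of two standardized maps is provided
for the exploratory one-map-as-control analysis; its interpretation caveats
are the user's to weigh.

## Synthetic worlds

`make_world` instantiates the named regimes. Violations target condition
(1,1): a tuning deviation `δ` of prescribed norm (drawn as a seeded random
unit direction times the effect size), or a covariance scaling of
`1 + effect_size`. The hidden-violation decoder is a unit vector drawn from
the null space of `δ` (minimum-norm particular solution plus seeded
null-space component, normalized); the exposed-violation decoder is the unit
vector along `δ`, so decoding means at target level 1 differ by exactly the
effect size — in units of the decoding SD when channel noise is 1. The
weight-angle regimes build additive signal directions for A and B at 90° or
45°. Defaults (4 channels, unit noise, 2×2 grid) are the simulation
conditions used throughout the calibration studies.

`generate_volume_dataset` plants a world's measured patterns inside a
sphere of a 3-D lattice via a seeded random mixing matrix scaled so its
Frobenius norm is `snr · error_sd · √M` (M signal voxels); all voxels carry
i.i.d. unit-variance Gaussian noise. `snr = 0` yields pure noise. The
generator emulates trial-wise activity estimates only: no hemodynamics, no
temporal or spatial autocorrelation, no run structure, no realistic face
stimuli. Passing tests therefore validate the statistical machinery under
the stated Gaussian world, not robustness to fMRI artifacts.

## Problem sizes and numerics

Calibration and power studies use 500 replicates (50 trials per condition
for null calibration, 100 for the violation scenarios); the planted-signal
volume is 20³ with a radius-4 signal sphere and 40 trials per condition.
Monte-Carlo checks of closed forms use 1e5 draws with 3-SE tolerances. KDE
kernel evaluation is chunked (4,096 samples at a time) to stay
cache-friendly at these sizes. Degenerate inputs fail loudly: constant
samples (zero range or zero SD), empty conditions, non-PSD covariances,
non-partitioning classifier regions, and zero weight vectors all raise
`ValueError` rather than returning NaN.

## Known limitations

Only two-level target dimensions are decoded (one-vs-one linear SVM);
maximum-likelihood or nonlinear decoders are not implemented. Encoding and
decoding *independence* are representable but have no test procedure here.
The standardized DDS is known to run conservative in some settings (the
proportion index can sit below 0.5 in data-rich regions); no correction is
applied beyond the optional differential contrast. Cluster-level group
correction is absent by design.
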