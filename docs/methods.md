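# Methods

## Forward model

A voxel holds n ∈ {1, 2, 3} fiber populations.  Each population i is a
biexponential pair of axially symmetric Gaussian compartments sharing
eigenvectors: a fast tensor D_i with eigenvalues (λ1, λ2, λ2) and a slow
tensor D̄_i with (λ3, λ4, λ4), mixed by the fast fraction w_i.  The
normalized attenuation along gradient direction u at b-value b is

    S(b, u) = (1/n) Σ_i [ w_i e^(−b uᵀD_i u) + (1 − w_i) e^(−b uᵀD̄_i u) ].

The 1/n prefactor keeps S(b=0, ·) = 1 for every fiber count, which is the
property a normalized attenuation model must have; with any fixed constant
prefactor the b=0 signal would depend on n.  Eigenvalues are stored in
μm²/ms and b in s/mm², so the exponent carries a factor 10⁻³ (at b = 1000
and λ = 2 the attenuation along the axis is e⁻²).  Per-fiber volume
fractions are deliberately absent (all fibers weigh 1/n); the fast/slow
split is the only compartment weighting.

The cylindrical tensor is assembled as D = λ2·I + (λ1 − λ2)·mmᵀ, which is
manifestly independent of how the orthonormal completion (p, v) of the
axis m is chosen; the completion helper exists only for tests and uses a
fixed reference axis (z, falling back to x within ~25° of z).

Implementation note: the per-fiber signal contributions are sorted before
averaging so that permuting the fiber blocks of α yields a bit-identical
signal — the fiber-exchange symmetry then holds exactly in floating point,
not just to rounding.

## Priors and sampling

All parameters are uniform on a box: θ, φ ∈ [0, π] (fiber axes are
antipodally symmetric, so a hemisphere of the parameterization suffices),
fast eigenvalues on [1, 3] μm²/ms with λ1 ≥ λ2, slow eigenvalues on
[0.1, 0.6] with λ3 ≥ λ4, and the fast fraction fixed at w = 0.7 (test-time
robustness to other values is measured separately).  Multi-fiber draws are
additionally constrained: fast-component FA > 0.2 per fiber, crossing
angle in [10°, 90°] for two fibers, all pairwise angles ≥ 45° for three.
Constraints are enforced by rejection sampling, which is exactly uniform
on the constrained set; eigenvalue ordering comes free from sorting two
i.i.d. uniforms.  Measurement noise is zero-mean Gaussian with σ = 0.04 on
the normalized signal (average SNR ≈ 3 at typical white-matter
attenuations); the Gaussian approximation to Rician noise is adequate
above that SNR, and Rician simulation is out of scope.

Note a consequence of the eigenvalue box: the largest attainable
fast-component FA is FA(3, 1) ≈ 0.603.  "High-FA" protocols therefore use
an FA ≥ 0.5 floor.

## ODF maps

Per shell (b = 1000, 2000, 3000 s/mm², 90 directions each in the synthetic
scheme), the signal is fit in the real symmetric even spherical-harmonic
basis up to order L = 8 (45 coefficients) by least squares with
Laplace–Beltrami regularization (penalty (l(l+1))², default weight 6e-3;
zero for exact-fit tests).  The analytic q-ball diffusion ODF follows by
scaling each degree-l coefficient with the Funk–Radon eigenvalue
2π P_l(0).

The plain q-ball ODF of this model is very smooth: at order 8 the lobes of
two crossing fibers merge into a single bisector ridge for crossings below
about 90°, carrying too little contrast for reliable 2-vs-3-fiber
discrimination.  The rendered maps therefore use a sharpened ODF: the
q-ball ODF is deconvolved per degree by the rotational harmonics of a
canonical high-anisotropy single-fiber response (λ = (3, 1, 0.5, 0.2),
w = 0.7, evaluated at the shell's b-value), with a mild Tikhonov factor
k/(k² + τ²), τ = 0.05·|k₂|, damping the near-null high degrees under
noise.  This is a fixed linear per-degree filter, identical at training
and inference; with it, 30–60° crossings produce distinct map maxima.
The un-sharpened Funk–Radon ODF remains available (`sharpen=False`) and is
what `compute_odf` returns.

The 2D map evaluates the three per-shell ODFs on a 32×32 cell-centered
grid over θ ∈ [0, π] × φ ∈ [0, 2π) (rows ↦ θ, columns ↦ φ; the full
sphere is kept, so the antipodal redundancy is visible in the map) and
min–max normalizes each channel to [0, 1].  A constant channel maps to
all zeros.  Only the ODF shape matters downstream, so the absolute scale
is deliberately discarded.

Peak finding seeds a 1000-point spiral hemisphere grid, refines the best
candidates by Nelder–Mead ascent on the SH expansion, folds antipodes,
merges peaks within 15° and drops peaks below 0.3 of the global maximum
(defaults; peaks are a diagnostic/baseline, not part of the estimation
path).

## Fiber-count classifier

Two conv/max-pool stages (5×5 kernels, 6 feature maps, padding 4, 2×2
pooling) take the 32×32×3 map to 6×11×11 = 726 features (the flatten size
is recomputed from the kernel/padding/pool arithmetic, not assumed),
followed by linear layers of width 1000, 500, 84 and a four-layer head
84→64→32→16→3.  Rectifier activations throughout; Kaiming-uniform
initialization.  The reference training recipe is SGD with momentum 0.95
and learning rate 1e-4 under cross-entropy; at desk scale that schedule
converges far too slowly, so the desk preset uses Adam at 1e-3 (12 epochs,
batch 100, 10% validation split, best-validation restore).  Training data
are balanced across the three classes.  The desk benchmark classifier is
trained on a half noiseless / half SNR-3 mixture: with only a few thousand
training voxels, a purely noisy training set leaves noiseless test maps
far out of distribution (the network collapses on them), while the
mixture keeps both benchmark conditions in-distribution.  Desk-scale
error rates on the hard benchmark protocol (10° two-fiber crossings at
SNR 3) remain far above the full-scale reference numbers, which require
orders of magnitude more training data; the benchmark driver reports
those reference values as metadata without claiming them.

## Posterior estimation

The posterior p(α | y) over the 6n parameters is approximated by a
Gaussian mixture with full covariances, conditioned on the ODF map through
a network with the same conv trunk as the classifier followed by seven
fully connected layers (hidden width 1000 in the reference configuration,
256 in the desk preset; dropout 0.1).  Because permuting fiber blocks
leaves the signal unchanged, the posterior has at least n! symmetric
modes; the mixture uses m = 5 components for n = 1 and 2 and m = 10 for
n = 3.  Three networks are trained, one per fiber count, routed by the
classifier at inference.

The head emits, per component, a weight logit, a mean, and a
lower-triangular Cholesky factor of the **precision** matrix whose
diagonal passes through exp (raw values clipped to ±8).  This guarantees
a symmetric positive-definite covariance for every finite head output;
covariances are recovered in Gram form Σ = C⁻ᵀC⁻¹ with a 1e-10 relative
diagonal jitter so strict positive definiteness survives floating point.
Gradients of the mixture negative log-likelihood are analytic and
verified against finite differences at 1e-8.

Training is single-round neural posterior estimation: the proposal equals
the prior, the importance ratio and normalization constant are unity, and
the loss is the negative mean log mixture density of the simulated α under
q_ψ(· | y).  Parameters are standardized to the prior box mapped to
[−1/2, 1/2]^d before density modeling (covariance conditioning) and
reported back in natural units, with the Jacobian included in reported
log-densities.  Angles are treated as plain bounded reals — no wrapped
distributions.  Reference schedule: batch 100, learning rate 5e-5, early
stopping with 30-epoch patience on a 10% validation split and
best-validation restore; the desk preset uses Adam at 5e-4 with the
train-size/epoch budgets below.

Separating the n! permutation modes is the expensive part of multi-fiber
training: a two-fiber network trained on 30,000 noiseless samples for 22
epochs (~30 min CPU) places its two dominant components on the true fiber
pair (either order, < 15°) for ~72% of test voxels with 6.5° median
angular error, while a 18,000×10-epoch budget leaves the components
blended (~7%) even though signal reconstruction is already accurate
(NMSE ≈ 0.03) — the inverse problem's near-equivalent solutions are found
before its mode structure is.  The default test suite therefore checks
the mode-coverage machinery on constructed mixtures and leaves the
trained-model capacity check to longer runs.

The point estimate is the dominant mixture component by
δᵢ = wᵢ·trace(Σᵢ^{1/2}) (principal matrix square root), largest δᵢ — the
rule as printed in the source method.  That statistic *grows* with
component variance, which conflicts with the stated motivation of
discarding high-variance components; the alternative rule
argmax wᵢ/trace(Σᵢ^{1/2}) is implemented behind `rule="inverse"`.  Both
reduce to argmax wᵢ for equal covariances.  The printed rule is the
default; the disagreement is surfaced rather than silently resolved.

## Derived measures and uncertainty propagation

Closed forms in the eigenvalues (units μm²/ms; diffusion-time constants
absorbed into the prefactors, so MSD/RTOP are comparable only within this
convention):

* FA of the fast tensor: sqrt((λ1−λ2)²/(λ1²+2λ2²))
* GFA of a signal shell: std(S)/rms(S), population std (divide by N) so
  GFA ∈ [0, 1] exactly; computed on the b = 1000 shell by default
* MSD: (1/n)·π²·Σᵢ[wᵢ(λ1ᵢ+2λ2ᵢ) + (1−wᵢ)(λ3ᵢ+2λ4ᵢ)]
* RTOP: (2/n)·π^{3/2}·Σᵢ[wᵢ/(λ2ᵢ√λ1ᵢ) + (1−wᵢ)/(λ4ᵢ√λ3ᵢ)]
  (inverse root determinant of the cylindrical tensor, det D = λ1λ2²)
* MD of the fast tensor: (λ1+2λ2)/3

Uncertainty in the eigenvalue sub-vector of the dominant component is
pushed through these nonlinear maps with the classical symmetric
unscented transform: 2d+1 sigma points μ and μ ± columns of √((d+κ)Σ)
(Cholesky), κ = 3 − d, center weight κ/(d+κ).  The transform is exact for
affine maps (tested to 1e-10) and matches 10⁵-sample Monte-Carlo within
5% for all four measures at prior-typical covariances.  Sigma points that
violate eigenvalue positivity are reflected about a small floor and
counted; with κ < 0 the variance estimate can round negative for strongly
nonlinear f, and is clamped at zero.  Angles never enter the measures.
ROI summaries offer both the arithmetic and the inverse-variance-weighted
mean.

## Baselines and evaluation metrics

Nonlinear least-squares fits of the forward model (fiber count fixed a
priori): Levenberg–Marquardt (unbounded) and trust-region-reflective with
the prior box as bounds, via `scipy.optimize.least_squares`, restarted
from prior-uniform initializations.  Restart estimates are clustered by
the principal fiber axis (10° radius); two or more clusters flag a
multi-modal solution set.

Angular error between fiber sets is arccos|⟨m̂, m⟩| per pair under the
total-error-minimizing permutation (exhaustive over n! ≤ 6; verified
against the Hungarian assignment).  Eigenvalue errors reuse that matching
and sum |λ̂ − λ| over fibers and eigenvalues; per-voxel means are used for
multi-fiber voxels.  NMSE is ‖est − ref‖²/‖ref‖².  Sweeps bin errors by a
covariate into 8 equal-width bins and report median with 25th/75th
percentiles; empty bins are reported, not dropped.

## Scale presets and reproducibility

The reference configuration (2×10⁶ training samples, hidden width 1000,
SGD schedules, 20,000-voxel test sets) is expressible in the configs but
is a multi-GPU-hour undertaking.  The desk presets used by the test suite
and the acceptance script are the package's CPU-scale choices:
classifier — 3×900–1000 training voxels, 8–12 epochs; posterior (n = 1) —
15,000–18,000 noiseless samples, hidden width 256, 8–10 epochs;
evaluation sets of 100–4,500 voxels; LM multi-start with 60 voxels × 20
restarts.  Under these budgets the desk runs achieve (seeds as in the
suite) ~2.7–4° median single-fiber angular error noiseless, ≥ 95%
well-separated classification accuracy, and 100% log-density recovery —
comfortably inside the floors the test suite asserts (< 10°, ≥ 0.95,
≥ 90%) but far
from the full-scale reference numbers, which desk runs report as metadata
without asserting.

Every stochastic stage receives a child seed spawned (SeedSequence) from
one master seed; datasets, training and evaluations are bit-reproducible
at fixed seed on one platform.  Checkpoints embed their config; the run
config round-trips through YAML and carries a content hash.

## What the synthetic generator does and does not emulate

The generator reproduces the acquisition geometry (three shells × 90
directions), the stated parameter priors and constraint structure, and
additive Gaussian noise at SNR ≈ 3.  It does not emulate Rician noise
floors, spatial correlation between voxels, fiber dispersion (only small
crossing angles stand in for it), gray-matter water exchange, partial
volume with CSF, or scanner artifacts.  Passing tests therefore
demonstrate correctness of the method under the model's own assumptions
and its noise robustness in distribution — not performance on real
acquisitions, for which the NIfTI path exists but is validated here only
on synthetic volumes.

## Known limitations

* The networks are plain-numpy with manual backprop; they are exact but
  CPU-bound, so full-scale replication is impractical in this repo.
* The 2-vs-3-fiber decision stays hard near the 45° three-fiber floor at
  SNR 3; desk-scale error rates there are well above the full-scale
  reference.
* Map sharpening assumes a single canonical fiber response; strongly
  atypical diffusivities are over- or under-sharpened (the classifier
  tolerates this; peak counting is more sensitive).
* The δᵢ selection-rule ambiguity above.
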