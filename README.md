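# dmri-posterior

Likelihood-free posterior estimation and uncertainty quantification for
multi-fiber diffusion MRI.

## The problem

Voxel-wise fitting of multi-compartment dMRI models is a badly conditioned
nonlinear inverse problem: at realistic noise levels (SNR ≈ 3) the
least-squares objective has many near-equivalent minima, so standard
Levenberg–Marquardt fits return different answers from different starting
points, and none of them comes with an uncertainty. This package targets
researchers who need *distributions* over microstructure parameters — and
over the derived measures used in group studies — rather than a single
point estimate of unknown reliability.

## The model and the method

Each voxel holds n ∈ {1,2,3} fiber populations. Population *i* is a pair of
axially symmetric Gaussian compartments sharing eigenvectors — a fast
tensor D_i with eigenvalues (λ1, λ2, λ2) and a slow tensor D̄_i with
(λ3, λ4, λ4) — mixed by a fast fraction w:

    S(b, u) = (1/n) Σ_i [ w e^(−b·uᵀD_i u) + (1−w) e^(−b·uᵀD̄_i u) ]

with λ in μm²/ms, b in s/mm² and α = [θ_i, φ_i, λ1_i..λ4_i]_{i=1..n} the
6n-dimensional parameter vector.

The pipeline is simulation-based inference:

1. **Forward simulation** draws α from a uniform box prior (fast
   eigenvalues [1,3], slow [0.1,0.6] μm²/ms, w = 0.7, crossing-angle and
   FA constraints for multi-fiber voxels) and simulates multi-shell
   signals (90 directions × b = 1000/2000/3000 s/mm², Gaussian noise
   σ = 0.04).
2. **ODF maps**: per shell, an order-8 spherical-harmonic fit and the
   Funk–Radon q-ball ODF, deconvolution-sharpened and rendered as a
   32×32×3 image in (θ, φ).
3. **Fiber-count classification**: a small CNN maps the ODF image to
   n ∈ {1,2,3}.
4. **Posterior estimation**: per fiber count, a mixture-density network
   emits a full-covariance Gaussian mixture q_ψ(α|y) = Σ_i w_i N(μ_i, Σ_i),
   trained with the single-round neural-posterior loss
   −Σ_j log q_ψ(α_j | y_j) on simulated pairs. The point estimate is the
   dominant component by δ_i = w_i·trace(Σ_i^½).
5. **Uncertainty propagation**: closed-form measures (FA, GFA, MSD, RTOP,
   MD) and their standard deviations via the unscented transform applied
   to the dominant component's eigenvalue covariance.

The networks are implemented in plain numpy with hand-derived,
finite-difference-verified backpropagation (including the full-covariance
MDN loss via a precision-Cholesky parameterization), so the package has no
deep-learning framework dependency.

## Worked example

```python
import numpy as np
from dmri_posterior import forward_model as fm, odf_maps as om
from dmri_posterior import posterior as pe, derived_measures as dm

scheme = fm.hcp_like_scheme(90)           # 3 shells x 90 directions
renderer = om.MapRenderer(scheme)
prior = fm.PriorSpec()

# train a desk-scale single-fiber posterior network (noiseless, ~6 min CPU)
cfg = pe.PosteriorNetConfig.desk(n_fibers=1, train_size=18_000,
                                 epochs=10, noise_sigma=0.0, seed=1235)
model = pe.train_posterior(cfg, prior, renderer)

# simulate a test voxel and estimate its posterior
alpha = fm.sample_prior_alphas(prior, 1, 1, np.random.default_rng(990))
maps = renderer.render_batch(fm.simulate_signals(alpha, 0.7, scheme))
est = model.estimate(maps[0])             # dominant mixture component

m_est = fm.spherical_to_unit(est.alpha[0], est.alpha[1])
m_true = fm.spherical_to_unit(alpha[0, 0], alpha[0, 1])
ang = np.degrees(np.arccos(abs(float(m_est @ m_true))))
print(f"angular error: {ang:.1f} deg")
print(f"lam1: {est.alpha[2]:.2f} +/- {est.std[2]:.2f} um^2/ms "
      f"(true {alpha[0,2]:.2f})")
fa = dm.propagate_measure("FA", est.alpha[2:6], est.cov[2:6, 2:6])
print(f"FA: {fa.mean:.3f} +/- {fa.std:.3f}")
```

Output from this exact script (seeds as shown):

```
angular error: 5.2 deg
lam1: 2.41 +/- 0.40 um^2/ms (true 2.11)
FA: 0.106 +/- 0.050
```

The angular error is the folded angle between the estimated and true fiber
axes; the ± values are posterior standard deviations. The drawn voxel
happens to be weakly anisotropic (true fast-component FA ≈ 0.14), which is
the hard regime for orientation recovery — the posterior reflects that
honestly: the λ1 interval covers the truth within one standard deviation,
and the propagated FA interval (0.106 ± 0.050) covers the true 0.14.
Across 100 such test voxels the desk-scale model reaches ~3° median
angular error (see the acceptance output below).

Command-line interface (`dmri-posterior simulate | train-classifier |
train-posterior | infer | measures | evaluate`) wraps the same library for
NIfTI + bval/bvec volumes; `simulate` writes datasets as a compressed
`.npz` (signals, maps, labels, per-voxel α, noise σ, seed) next to the
YAML run config that regenerates them.

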