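"""End-to-end experiment drivers for the simulation benchmarks.

Each driver assembles the test protocol (prior constraints, noise level,
sample size), trains or reuses desk-scale networks, and returns rows for a
CSV table.  Reference results from the full-scale configuration (2×10⁶
training samples, GPU-hours of training) are kept here as
machine-readable bounds; they are asserted only by full-scale runs, while
desk-scale rows simply report them alongside the measured values.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np

from . import classifier as clf
from . import evaluation as ev
from . import forward_model as fm
from . import posterior as pe
from .io_utils import RunConfig, make_fixture, spawn_seeds

__all__ = [
    "FULL_SCALE_BOUNDS",
    "well_separated_prior",
    "sample_high_fa_singles",
    "classifier_benchmark",
    "weight_mismatch_benchmark",
    "sweep_experiment",
    "baseline_multimodality_experiment",
]

#: Full-scale reference performance (20,000-sample test protocol):
#: per-class misclassification (%) at SNR 3, and the matched-weights row of
#: the weight-mismatch experiment (mean angular error in degrees, mean
#: absolute total eigenvalue error in μm²/ms).
FULL_SCALE_BOUNDS = {
    "misclassification_snr3_pct": {1: 2.7, 2: 2.3, 3: 4.7},
    "weight_matched_angular_deg": 2.93,
    "weight_matched_eigenvalue_um2_ms": 0.07,
}


def well_separated_prior(min_angle: float = 60.0) -> fm.PriorSpec:
    """Multi-fiber prior restricted to wide crossings (easy protocol)."""
    return dataclasses.replace(
        fm.PriorSpec(),
        min_angle_deg={1: 0.0, 2: min_angle, 3: min_angle})


def sample_high_fa_singles(count: int, seed, fa_min: float = 0.5,
                           prior: fm.PriorSpec = None) -> np.ndarray:
    """Single-fiber α draws with fast-component FA above ``fa_min``.

    The prior's eigenvalue box caps the axial FA at FA(3, 1) ≈ 0.60, so
    ``fa_min`` must stay below that for the draw to be feasible.
    """
    prior = prior or fm.PriorSpec()
    rng = np.random.default_rng(seed)
    out, need = [], count
    for _ in range(200):
        a = fm.sample_prior_alphas(prior, 1, 3 * need + 64, rng)
        fa = np.sqrt((a[:, 2] - a[:, 3]) ** 2
                     / (a[:, 2] ** 2 + 2 * a[:, 3] ** 2))
        good = a[fa > fa_min][:need]
        out.append(good)
        need -= good.shape[0]
        if need == 0:
            return np.vstack(out)
    raise RuntimeError(f"FA floor {fa_min} infeasible under the prior")


def _test_protocol_sets(cfg: RunConfig, renderer, n_per_class: int, seed,
                        noise_sigma: float):
    """Test voxels per the benchmark protocol: n=1 unconstrained FA,
    n=2 crossing 10–90°, n=3 pairwise ≥ 45°, FA > 0.2 for multi-fiber."""
    prior = cfg.prior_spec()
    seeds = spawn_seeds(seed, 6)
    maps, labels = [], []
    for j, n in enumerate((1, 2, 3)):
        a = fm.sample_prior_alphas(prior, n, n_per_class,
                                   np.random.default_rng(seeds[2 * j]))
        s = fm.simulate_signals(a, prior.w_fast, renderer.scheme)
        if noise_sigma > 0:
            s = s + np.random.default_rng(seeds[2 * j + 1]).normal(
                0.0, noise_sigma, s.shape)
        maps.append(renderer.render_batch(s))
        labels.append(np.full(n_per_class, n))
    return np.concatenate(maps), np.concatenate(labels)


def train_desk_classifier(cfg: RunConfig, renderer=None,
                          per_class: int = None,
                          noise_sigma: float = None):
    """Desk-scale classifier trained on the benchmark prior.

    Training mixes noiseless and noisy voxels half/half so both clean and
    SNR-3 test maps lie in the training distribution — at small sample
    budgets a purely noisy training set leaves noiseless maps badly out of
    distribution.
    """
    renderer = renderer or cfg.renderer()
    per_class = per_class or cfg.classifier_train_per_class
    sigma = cfg.noise_sigma if noise_sigma is None else noise_sigma
    seeds = spawn_seeds(cfg.master_seed + 101, 3)
    half = max(1, per_class // 2)
    ds_noisy = make_fixture(cfg.prior_spec(), renderer,
                            {1: half, 2: half, 3: half},
                            seeds[0], noise_sigma=sigma)
    ds_clean = make_fixture(cfg.prior_spec(), renderer,
                            {1: per_class - half, 2: per_class - half,
                             3: per_class - half},
                            seeds[1], noise_sigma=0.0)
    maps = np.concatenate([ds_noisy.maps, ds_clean.maps])
    labels = np.concatenate([ds_noisy.labels, ds_clean.labels])
    net_cfg = clf.ClassifierConfig.desk(epochs=cfg.classifier_epochs,
                                        seed=seeds[2])
    return clf.train_classifier(clf.build_classifier(net_cfg), maps,
                                labels, net_cfg)


def classifier_benchmark(cfg: RunConfig, n_test: int = 500,
                         model=None) -> dict:
    """Per-class misclassification, noiseless and at SNR 3.

    Desk-scale replication of the classifier benchmark; the full-scale
    SNR-3 bounds are attached to each row for reference and are asserted
    only when ``cfg.scale == "full"``.
    """
    renderer = cfg.renderer()
    if model is None:
        model = train_desk_classifier(cfg, renderer)
    rows = []
    per = max(1, n_test // 3)
    for sigma, tag in ((0.0, "noiseless"), (cfg.noise_sigma, "snr3")):
        maps, labels = _test_protocol_sets(cfg, renderer, per,
                                           cfg.master_seed + 202, sigma)
        pred = clf.predict_labels(model, maps)
        table = clf.misclassification_table(pred, labels)
        for n, cell in table.items():
            bound = FULL_SCALE_BOUNDS["misclassification_snr3_pct"][n]
            row = {"condition": tag, "n_fibers": n,
                   "misclassification_pct": 100.0 * cell["error"],
                   "n_test": cell["count"],
                   "full_scale_bound_pct": bound if tag == "snr3" else None}
            if cfg.scale == "full" and tag == "snr3":
                row["bound_satisfied"] = bool(
                    row["misclassification_pct"] <= bound)
            rows.append(row)
    return {"rows": rows, "scale": cfg.scale,
            "full_scale_bounds": FULL_SCALE_BOUNDS}


def _posterior_point_estimator(model: pe.PosteriorModel, renderer):
    def estimate(signals: np.ndarray) -> list:
        maps = renderer.render_batch(signals)
        return [model.estimate(maps[i]).alpha for i in range(maps.shape[0])]
    return estimate


def weight_mismatch_benchmark(cfg: RunConfig, n_test: int = 200,
                              model: pe.PosteriorModel = None,
                              n_fibers: int = 2,
                              test_weights=(0.5, 0.6, 0.7, 0.8, 0.9)) -> dict:
    """Robustness to fast/slow-fraction mismatch (trained at w = 0.7)."""
    renderer = cfg.renderer()
    prior = cfg.prior_spec()
    if model is None:
        net_cfg = pe.PosteriorNetConfig.desk(
            n_fibers=n_fibers, train_size=cfg.posterior_train_size,
            epochs=cfg.posterior_epochs, noise_sigma=cfg.noise_sigma,
            seed=cfg.master_seed + 303)
        model = pe.train_posterior(net_cfg, prior, renderer)
    estimator = _posterior_point_estimator(model, renderer)
    rows = ev.weight_mismatch_experiment(
        estimator, renderer.scheme, prior, n_fibers,
        test_weights=test_weights, n_test=n_test,
        noise_sigma=cfg.noise_sigma, seed=cfg.master_seed + 404)
    for row in rows:
        if abs(row["w_fast"] - prior.w_fast) < 1e-9:
            row["full_scale_bound_angular_deg"] = \
                FULL_SCALE_BOUNDS["weight_matched_angular_deg"]
            row["full_scale_bound_eigenvalue"] = \
                FULL_SCALE_BOUNDS["weight_matched_eigenvalue_um2_ms"]
            if cfg.scale == "full":
                row["bound_satisfied"] = bool(
                    row["angular_error_deg"]
                    <= FULL_SCALE_BOUNDS["weight_matched_angular_deg"]
                    and row["eigenvalue_error_total"]
                    <= FULL_SCALE_BOUNDS["weight_matched_eigenvalue_um2_ms"])
    return {"rows": rows, "scale": cfg.scale,
            "full_scale_bounds": FULL_SCALE_BOUNDS}


def sweep_experiment(cfg: RunConfig, which: str, n_test: int = 500,
                     model: pe.PosteriorModel = None) -> dict:
    """Angular-error sweeps (vs FA or crossing angle) or an NMSE summary."""
    renderer = cfg.renderer()
    prior = cfg.prior_spec()
    n_fibers = 2 if which == "sweep-angle" else 1
    if model is None:
        net_cfg = pe.PosteriorNetConfig.desk(
            n_fibers=n_fibers, train_size=cfg.posterior_train_size,
            epochs=cfg.posterior_epochs, noise_sigma=cfg.noise_sigma,
            seed=cfg.master_seed + 505)
        model = pe.train_posterior(net_cfg, prior, renderer)
    seeds = spawn_seeds(cfg.master_seed + 606, 2)
    alphas = fm.sample_prior_alphas(prior, n_fibers, n_test,
                                    np.random.default_rng(seeds[0]))
    clean = fm.simulate_signals(alphas, prior.w_fast, renderer.scheme)
    signals = clean + np.random.default_rng(seeds[1]).normal(
        0.0, cfg.noise_sigma, clean.shape) if cfg.noise_sigma > 0 else clean
    maps = renderer.render_batch(signals)
    est = [model.estimate(maps[i]).alpha for i in range(n_test)]
    ang = np.array([ev.eigenvalue_error(e, a)["angular"].mean
                    for e, a in zip(est, alphas)])
    if which == "nmse":
        recon = fm.simulate_signals(np.array(est), prior.w_fast,
                                    renderer.scheme)
        vals = np.array([ev.nmse(recon[i], clean[i])
                         for i in range(n_test)])
        return {"rows": [{"metric": "nmse", "median": float(np.median(vals)),
                          "p25": float(np.percentile(vals, 25)),
                          "p75": float(np.percentile(vals, 75)),
                          "n_test": n_test}],
                "scale": cfg.scale}
    if which == "sweep-fa":
        covar = np.sqrt((alphas[:, 2] - alphas[:, 3]) ** 2
                        / (alphas[:, 2] ** 2 + 2 * alphas[:, 3] ** 2))
        name = "fa_fast"
    elif which == "sweep-angle":
        m1 = fm.spherical_to_unit(alphas[:, 0], alphas[:, 1])
        m2 = fm.spherical_to_unit(alphas[:, 6], alphas[:, 7])
        covar = np.degrees(np.arccos(
            np.abs(np.einsum("ij,ij->i", m1, m2)).clip(0, 1)))
        name = "crossing_angle_deg"
    else:
        raise ValueError(f"unknown sweep '{which}'")
    sweep = ev.run_sweep(covar, ang, name)
    rows = [{"bin_center": float(c), "median_deg": float(m),
             "p25_deg": float(lo), "p75_deg": float(hi), "count": int(k)}
            for c, m, lo, hi, k in zip(sweep.bin_centers, sweep.median,
                                       sweep.p25, sweep.p75, sweep.counts)]
    return {"rows": rows, "scale": cfg.scale, "variable": name}


def permutation_mode_capacity(posterior, true_alpha: np.ndarray,
                              match_deg: float = 15.0) -> bool:
    """Do the two largest-δ components cover the true fiber pair?

    For a two-fiber MixturePosterior, checks whether either of the two
    top components by δᵢ = wᵢ·trace(Σᵢ^{1/2}) has both orientation means
    within ``match_deg`` of the true pair (in either fiber order) — the
    capacity the n! ≥ 2 mixture components exist to provide.  Separating
    the permutation modes requires far more training than the desk-scale
    budgets; this check is meaningful on full-scale models.
    """
    from scipy.linalg import sqrtm

    from . import evaluation as ev_mod

    true = np.asarray(true_alpha, dtype=float).reshape(2, 6)
    true_dirs = np.array([fm.spherical_to_unit(t[0], t[1]) for t in true])
    deltas = [posterior.weights[k]
              * float(np.trace(np.real(sqrtm(posterior.covs[k]))))
              for k in range(posterior.n_components)]
    for k in np.argsort(deltas)[::-1][:2]:
        mu = posterior.means[k].reshape(2, 6)
        est_dirs = np.array([fm.spherical_to_unit(m[0], m[1]) for m in mu])
        report = ev_mod.angular_error(est_dirs, true_dirs)
        if np.all(report.per_fiber < match_deg):
            return True
    return False


def run_pipeline(classifier_model, posteriors: dict, signals: np.ndarray,
                 renderer, w_fast: float = 0.7) -> dict:
    """Full voxel-wise pipeline: classify n, estimate α, reconstruct signal.

    ``posteriors`` maps fiber count → trained PosteriorModel.  Returns
    predicted labels, per-voxel dominant-component estimates, and the NMSE
    between the reconstructed (forward-modeled) and input signals.
    """
    from . import evaluation as ev_mod

    maps = renderer.render_batch(signals)
    labels = clf.predict_labels(classifier_model, maps)
    estimates, nmse_vals = [], []
    for i, n in enumerate(labels):
        est = posteriors[int(n)].estimate(maps[i])
        estimates.append(est)
        recon = fm.simulate_signals(est.alpha[None, :], w_fast,
                                    renderer.scheme)[0]
        nmse_vals.append(ev_mod.nmse(recon, signals[i]))
    return {"labels": labels, "estimates": estimates,
            "nmse": np.asarray(nmse_vals)}


def baseline_multimodality_experiment(cfg: RunConfig, n_voxels: int = 60,
                                      n_restarts: int = 20,
                                      n_fibers: int = 2) -> dict:
    """Restart-to-restart spread of the nonlinear LM fit at SNR 3.

    For each noisy two-fiber voxel, the LM fit is run from prior-uniform
    starts; voxels whose restart estimates fall into ≥ 2 orientation
    clusters (> 10° apart) demonstrate the multi-modality of the inverse
    problem.
    """
    prior = cfg.prior_spec()
    scheme = cfg.scheme()
    seeds = spawn_seeds(cfg.master_seed + 707, n_voxels + 2)
    alphas = fm.sample_prior_alphas(prior, n_fibers, n_voxels,
                                    np.random.default_rng(seeds[-1]))
    clean = fm.simulate_signals(alphas, prior.w_fast, scheme)
    noisy = clean + np.random.default_rng(seeds[-2]).normal(
        0.0, cfg.noise_sigma, clean.shape)
    n_multi = 0
    cluster_counts = []
    for i in range(n_voxels):
        sig = fm.Signal(values=noisy[i], scheme=scheme)
        fit_cfg = ev.BaselineFitConfig(method="lm", n_restarts=n_restarts,
                                       seed=seeds[i])
        result = ev.multi_start_fit(sig, n_fibers, fit_cfg, prior)
        good = [f["alpha"] for f in result["restarts"]
                if f["success"] and f["alpha"] is not None]
        k = ev.count_solution_clusters(good) if good else 0
        cluster_counts.append(k)
        n_multi += int(k >= 2)
    frac = n_multi / n_voxels
    return {"rows": [{"n_voxels": n_voxels, "n_restarts": n_restarts,
                      "fraction_multimodal": frac,
                      "mean_clusters": float(np.mean(cluster_counts))}],
            "fraction_multimodal": frac, "scale": cfg.scale}
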