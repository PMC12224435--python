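"""Mixture-posterior representation, loss and sampling tests."""

import math

import numpy as np
import pytest

from dmri_posterior import forward_model as fm
from dmri_posterior import posterior as pe
from dmri_posterior.nn.layers import Linear, ReLU, Sequential
from dmri_posterior.nn.losses import MdnNll
from dmri_posterior.nn.optim import Adam


def toy_mixture(d=2):
    means = np.array([np.zeros(d), np.full(d, 2.0)])
    covs = np.array([np.eye(d) * 0.5, np.eye(d) * 0.8])
    return pe.MixturePosterior(weights=np.array([0.7, 0.3]), means=means,
                               covs=covs)


class TestMdnDensity:
    def test_single_component_matches_closed_form(self):
        from scipy.stats import multivariate_normal
        mean = np.array([0.5, -0.2, 1.0])
        cov = np.array([[0.3, 0.05, 0.0], [0.05, 0.2, 0.02],
                        [0.0, 0.02, 0.4]])
        post = pe.MixturePosterior(weights=np.array([1.0]),
                                   means=mean[None], covs=cov[None])
        x = np.array([0.4, 0.0, 0.8])
        assert pe.mdn_density(post, x) == pytest.approx(
            multivariate_normal(mean, cov).pdf(x), rel=1e-10)

    def test_one_dimensional_mixture_integrates_to_one(self):
        # oracle: trapezoidal quadrature over a wide support
        post = pe.MixturePosterior(
            weights=np.array([0.4, 0.6]),
            means=np.array([[-1.0], [2.0]]),
            covs=np.array([[[0.5]], [[1.2]]]))
        xs = np.linspace(-12, 14, 8001)
        dens = np.array([pe.mdn_density(post, [x]) for x in xs])
        integral = np.trapezoid(dens, xs)
        assert integral == pytest.approx(1.0, abs=1e-4)

    def test_density_higher_at_mode_than_in_tail(self):
        post = toy_mixture()
        at_mode = pe.mdn_density(post, post.means[0])
        far = pe.mdn_density(post, post.means[0] + 50.0)
        assert at_mode > far

    def test_singular_covariance_rejected(self):
        post = pe.MixturePosterior(weights=np.array([1.0]),
                                   means=np.zeros((1, 2)),
                                   covs=np.zeros((1, 2, 2)))
        with pytest.raises(np.linalg.LinAlgError):
            pe.mdn_density(post, np.zeros(2))


class TestHeadToMixture:
    def test_zero_logits_give_uniform_weights(self):
        head = MdnNll(3, 5)
        raw = np.zeros((1, head.head_size))
        weights, _, _ = head.mixture_moments(raw)
        np.testing.assert_allclose(weights[0], 0.2, atol=1e-12)

    def test_zero_raw_factors_give_identity_covariance(self):
        head = MdnNll(3, 2)
        raw = np.zeros((1, head.head_size))
        _, _, covs = head.mixture_moments(raw)
        for c in covs[0]:
            np.testing.assert_allclose(c, np.eye(3), atol=1e-10)

    def test_random_heads_always_yield_spd_covariances(self):
        head = MdnNll(6, 5)
        rng = np.random.default_rng(0)
        for _ in range(300):
            raw = rng.normal(0, 3, (1, head.head_size))
            weights, _, covs = head.mixture_moments(raw)
            assert weights.sum() == pytest.approx(1.0, abs=1e-9)
            assert np.all(weights >= 0)
            for c in covs[0]:
                assert np.linalg.eigvalsh(c).min() > 0

    def test_non_finite_head_rejected(self):
        head = MdnNll(2, 2)
        raw = np.zeros((1, head.head_size))
        raw[0, 0] = np.nan
        with pytest.raises(ValueError):
            head.mixture_moments(raw)


class TestSnpeLoss:
    def test_loss_equals_negative_mean_log_density(self):
        head = MdnNll(4, 3)
        rng = np.random.default_rng(1)
        raw = rng.normal(0, 0.5, (16, head.head_size))
        z = rng.uniform(-0.5, 0.5, (16, 4))
        loss, _ = pe.snpe_loss(head, raw, z)
        assert loss == pytest.approx(-head.log_density(raw, z).mean(),
                                     abs=1e-10)

    def test_duplicated_batch_leaves_mean_loss_unchanged(self):
        head = MdnNll(3, 2)
        rng = np.random.default_rng(2)
        raw = rng.normal(0, 0.5, (8, head.head_size))
        z = rng.uniform(-0.5, 0.5, (8, 3))
        loss1, _ = pe.snpe_loss(head, raw, z)
        loss2, _ = pe.snpe_loss(head, np.vstack([raw, raw]),
                                np.vstack([z, z]))
        assert loss1 == pytest.approx(loss2, abs=1e-12)

    def test_concentrated_density_gives_strongly_negative_loss(self):
        head = MdnNll(2, 1)
        raw = np.zeros((4, head.head_size))
        # head layout for (d=2, m=1): [logit | mean (2) | log diag (2) | off]
        raw[:, 3:5] = 4.0  # log precision diag → tiny variance
        z = np.zeros((4, 2))  # targets at the component mean
        loss, _ = pe.snpe_loss(head, raw, z)
        assert loss < -3.0

    def test_alpha_outside_prior_box_rejected(self):
        head = MdnNll(2, 1)
        raw = np.zeros((1, head.head_size))
        with pytest.raises(ValueError):
            pe.snpe_loss(head, raw, np.array([[0.8, 0.0]]))

    def test_one_dimensional_toy_fit_improves_loss(self):
        # optimization sanity: a tiny MDN head on a fixed conditioning input
        rng = np.random.default_rng(3)
        head = MdnNll(1, 2)
        net = Sequential(Linear(1, 16, rng, dtype=np.float64), ReLU(),
                         Linear(16, head.head_size, rng, dtype=np.float64))
        x = np.ones((256, 1))
        targets = rng.normal(0.1, 0.05, (256, 1)).clip(-0.49, 0.49)
        raw0 = net.forward(x)
        loss0, _ = head.loss_and_grad(raw0, targets)
        opt = Adam(net.params(), 1e-2)
        for _ in range(150):
            raw = net.forward(x, train=True)
            loss, grad = head.loss_and_grad(raw, targets)
            net.backward(grad)
            opt.step()
        assert loss < loss0


class TestDominantComponent:
    def test_single_component_selected(self):
        post = pe.MixturePosterior(weights=np.array([1.0]),
                                   means=np.zeros((1, 2)),
                                   covs=np.eye(2)[None])
        est = pe.select_dominant_component(post)
        assert est.component == 0

    def test_equal_covariances_reduce_to_weight_argmax(self):
        post = pe.MixturePosterior(
            weights=np.array([0.2, 0.5, 0.3]),
            means=np.arange(6.0).reshape(3, 2),
            covs=np.stack([np.eye(2)] * 3))
        for rule in ("printed", "inverse"):
            assert pe.select_dominant_component(post, rule).component == 1

    def test_printed_and_inverse_rules_disagree_on_wide_component(self):
        # δ = w·trace(Σ^{1/2}): Σ₁=I gives δ₁=3, Σ₂=4I gives δ₂=6 in 6-D
        post = pe.MixturePosterior(
            weights=np.array([0.5, 0.5]),
            means=np.zeros((2, 6)),
            covs=np.stack([np.eye(6), 4.0 * np.eye(6)]))
        assert pe.select_dominant_component(post, "printed").component == 1
        assert pe.select_dominant_component(post, "inverse").component == 0

    def test_out_of_support_flags(self):
        post = pe.MixturePosterior(
            weights=np.array([1.0]),
            means=np.array([[0.5, 0.5, 4.5, 2.0, 0.4, 0.2]]),
            covs=np.eye(6)[None] * 0.01)
        est = pe.select_dominant_component(
            post, prior_bounds=fm.PriorSpec().bounds(1))
        assert est.out_of_support[2]  # λ1 = 4.5 above the prior box
        assert not est.out_of_support[0]


class TestPermutationModeCapacity:
    """The mode-coverage check itself, on constructed mixtures."""

    @staticmethod
    def _two_fiber_posterior(mean_a, mean_b, spread):
        means = np.stack([mean_a, mean_b, 0.5 * (mean_a + mean_b)])
        covs = np.stack([np.eye(12) * s for s in (0.01, 0.01, spread)])
        return pe.MixturePosterior(weights=np.array([0.45, 0.45, 0.10]),
                                   means=means, covs=covs)

    def test_mode_covering_mixture_detected(self):
        from dmri_posterior.experiments import permutation_mode_capacity
        f1 = np.array([0.3, 0.4, 2.0, 1.2, 0.5, 0.2])
        f2 = np.array([1.3, 1.1, 2.5, 1.5, 0.4, 0.3])
        alpha = np.concatenate([f1, f2])
        swapped = np.concatenate([f2, f1])
        post = self._two_fiber_posterior(alpha, swapped, 0.01)
        assert permutation_mode_capacity(post, alpha)

    def test_blended_mixture_not_credited(self):
        from dmri_posterior.experiments import permutation_mode_capacity
        f1 = np.array([0.2, 0.4, 2.0, 1.2, 0.5, 0.2])
        f2 = np.array([1.4, 1.1, 2.5, 1.5, 0.4, 0.3])
        alpha = np.concatenate([f1, f2])
        blend = np.concatenate([0.5 * (f1 + f2)] * 2)
        post = self._two_fiber_posterior(blend, blend, 0.01)
        assert not permutation_mode_capacity(post, alpha)


class TestSampling:
    def test_component_frequencies_converge_to_weights(self):
        post = pe.MixturePosterior(
            weights=np.array([0.7, 0.3]),
            means=np.array([[0.0], [100.0]]),
            covs=np.array([[[1.0]], [[1.0]]]))
        draws = pe.sample_posterior(post, 100_000, seed=5)
        frac = np.mean(draws[:, 0] < 50.0)
        assert frac == pytest.approx(0.7, abs=0.01)

    def test_vanishing_covariance_collapses_to_means(self):
        post = pe.MixturePosterior(
            weights=np.array([0.5, 0.5]),
            means=np.array([[1.0, 2.0], [3.0, 4.0]]),
            covs=np.stack([np.eye(2) * 1e-30] * 2))
        draws = pe.sample_posterior(post, 100, seed=6)
        dist_to_mean = np.minimum(
            np.linalg.norm(draws - post.means[0], axis=1),
            np.linalg.norm(draws - post.means[1], axis=1))
        assert dist_to_mean.max() < 1e-10

    def test_seeded_sampling_is_reproducible(self):
        post = toy_mixture()
        a = pe.sample_posterior(post, 500, seed=7)
        b = pe.sample_posterior(post, 500, seed=7)
        assert np.array_equal(a, b)


class TestTrainingLoop:
    def test_tiny_training_run_is_deterministic(self, prior, renderer):
        cfg = pe.PosteriorNetConfig.desk(n_fibers=1, train_size=600,
                                         epochs=2, noise_sigma=0.0, seed=11)
        losses = []
        for _ in range(2):
            model = pe.train_posterior(cfg, prior, renderer)
            losses.append(model.log.val_loss[-1])
        assert losses[0] == losses[1]

    def test_posterior_for_map_has_valid_mixture(self, prior, renderer,
                                                 scheme):
        cfg = pe.PosteriorNetConfig.desk(n_fibers=1, train_size=600,
                                         epochs=2, noise_sigma=0.0, seed=12)
        model = pe.train_posterior(cfg, prior, renderer)
        alphas = fm.sample_prior_alphas(prior, 1, 1,
                                        np.random.default_rng(13))
        sig = fm.simulate_signals(alphas, prior.w_fast, scheme)
        post = model.posterior_for_map(renderer.render_batch(sig)[0])
        assert post.n_components == 5
        assert post.weights.sum() == pytest.approx(1.0, abs=1e-9)
        for c in post.covs:
            assert np.linalg.eigvalsh(c).min() > 0

    def test_save_load_roundtrip_preserves_outputs(self, prior, renderer,
                                                   scheme, tmp_path):
        cfg = pe.PosteriorNetConfig.desk(n_fibers=1, train_size=600,
                                         epochs=1, noise_sigma=0.0, seed=14)
        model = pe.train_posterior(cfg, prior, renderer)
        alphas = fm.sample_prior_alphas(prior, 1, 3,
                                        np.random.default_rng(15))
        maps = renderer.render_batch(
            fm.simulate_signals(alphas, prior.w_fast, scheme))
        ref = model.raw_head(maps)
        path = tmp_path / "model.pkl"
        model.save(path)
        loaded = pe.PosteriorModel.load(path)
        np.testing.assert_array_equal(loaded.raw_head(maps), ref)
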