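"""Likelihood-free posterior estimation with a mixture-density network.

The posterior p(α | y) over the 6n-dimensional voxel parameters α is
approximated by a Gaussian mixture q_ψ(α | y) = Σᵢ wᵢ(y) N(α; μᵢ(y), Σᵢ(y))
whose parameters ψ are emitted by a convolutional network conditioned on the
voxel's 32×32×3 ODF map y.  Training is single-round neural posterior
estimation: with the proposal equal to the prior, the importance-ratio
correction is unity and the loss is the plain negative mean log mixture
density of the simulated α under q_ψ(· | y).

Because fiber blocks of α can be permuted without changing the signal, the
posterior has at least n! symmetric modes; the mixture therefore carries
m ≥ n! components (defaults 5, 5, 10 for n = 1, 2, 3).  Densities are
modeled in a standardized parameter space (prior box mapped to
[-1/2, 1/2]^6n) and reported back in natural units.
"""

from __future__ import annotations

import math
import pickle
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import sqrtm

from .forward_model import PriorSpec, sample_prior_alphas, simulate_signals
from .nn.layers import (Conv2d, Dropout, Flatten, Linear, MaxPool2d, ReLU,
                        Sequential)
from .nn.losses import MdnNll
from .nn.optim import make_optimizer
from .nn.training import EarlyStopper, TrainLog, iterate_minibatches
from .odf_maps import MAP_SHAPE, MapRenderer

__all__ = [
    "MixturePosterior",
    "PosteriorNetConfig",
    "ParameterEstimate",
    "PosteriorModel",
    "default_n_components",
    "mdn_density",
    "snpe_loss",
    "build_posterior_net",
    "train_posterior",
    "select_dominant_component",
    "sample_posterior",
    "SimulatedDataset",
    "make_training_data",
]


def default_n_components(n_fibers: int) -> int:
    """m ≥ n! symmetric modes: 5 components for 1–2 fibers, 10 for 3."""
    return {1: 5, 2: 5, 3: 10}[n_fibers]


@dataclass(frozen=True)
class MixturePosterior:
    """Gaussian mixture over α in natural units (rad, μm²/ms)."""

    weights: np.ndarray  # (m,)
    means: np.ndarray  # (m, d)
    covs: np.ndarray  # (m, d, d)

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        mu = np.asarray(self.means, dtype=float)
        cov = np.asarray(self.covs, dtype=float)
        if w.ndim != 1 or mu.shape[0] != w.size or cov.shape[:2] != (w.size, mu.shape[1]):
            raise ValueError("inconsistent mixture shapes")
        if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-6:
            raise ValueError("weights must be non-negative and sum to 1")
        if not np.allclose(cov, np.swapaxes(cov, -1, -2), atol=1e-8):
            raise ValueError("covariances must be symmetric")
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "means", mu)
        object.__setattr__(self, "covs", cov)

    @property
    def n_components(self) -> int:
        return int(self.weights.size)

    @property
    def dim(self) -> int:
        return int(self.means.shape[1])


def mdn_density(post: MixturePosterior, alpha) -> float:
    """Mixture density Σᵢ wᵢ N(α; μᵢ, Σᵢ) at one parameter vector."""
    alpha = np.asarray(alpha, dtype=float).ravel()
    if alpha.size != post.dim:
        raise ValueError(f"alpha must have dimension {post.dim}")
    total = 0.0
    for w, mu, cov in zip(post.weights, post.means, post.covs):
        chol = np.linalg.cholesky(cov)  # raises on singular Σ
        z = np.linalg.solve(chol, alpha - mu)
        log_det = 2.0 * np.log(np.diag(chol)).sum()
        log_pdf = -0.5 * (post.dim * math.log(2.0 * math.pi) + log_det
                          + float(z @ z))
        total += w * math.exp(log_pdf)
    return total


def sample_posterior(post: MixturePosterior, k: int, seed) -> np.ndarray:
    """Ancestral sampling: component by weight, then a Gaussian draw."""
    if k < 1:
        raise ValueError("need k >= 1 samples")
    rng = np.random.default_rng(seed)
    comp = rng.choice(post.n_components, size=k, p=post.weights)
    out = np.empty((k, post.dim))
    for i in range(post.n_components):
        mask = comp == i
        if not np.any(mask):
            continue
        out[mask] = rng.multivariate_normal(
            post.means[i], post.covs[i], size=int(mask.sum()),
            method="cholesky" if _is_pd(post.covs[i]) else "svd")
    return out


def _is_pd(cov: np.ndarray) -> bool:
    try:
        np.linalg.cholesky(cov)
        return True
    except np.linalg.LinAlgError:
        return False


@dataclass(frozen=True)
class ParameterEstimate:
    """Point estimate from the dominant mixture component."""

    component: int
    alpha: np.ndarray  # (6n,) natural units
    std: np.ndarray  # (6n,) sqrt of the Σ diagonal
    cov: np.ndarray  # (6n, 6n)
    out_of_support: np.ndarray = None  # bool flags vs. the prior box

    def __post_init__(self) -> None:
        object.__setattr__(self, "alpha", np.asarray(self.alpha, dtype=float))
        object.__setattr__(self, "std", np.asarray(self.std, dtype=float))


def select_dominant_component(post: MixturePosterior, rule: str = "printed",
                              prior_bounds=None) -> ParameterEstimate:
    """Pick the mixture component that serves as the point estimate.

    The selection statistic is δᵢ = wᵢ·trace(Σᵢ^{1/2}) with the principal
    matrix square root.  ``rule="printed"`` takes the largest δᵢ;
    ``rule="inverse"`` takes the largest wᵢ/trace(Σᵢ^{1/2}), which instead
    penalizes high-variance components.  Both reduce to argmax wᵢ when all
    covariances are equal.
    """
    traces = np.array([float(np.trace(np.real(sqrtm(c)))) for c in post.covs])
    if rule == "printed":
        scores = post.weights * traces
    elif rule == "inverse":
        scores = post.weights / traces
    else:
        raise ValueError("rule must be 'printed' or 'inverse'")
    k = int(np.argmax(scores))
    alpha = post.means[k]
    flags = None
    if prior_bounds is not None:
        lo, hi = prior_bounds
        flags = (alpha < lo) | (alpha > hi)
    return ParameterEstimate(component=k, alpha=alpha,
                             std=np.sqrt(np.diag(post.covs[k])),
                             cov=post.covs[k], out_of_support=flags)


# --------------------------------------------------------------------------
# network
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PosteriorNetConfig:
    """Posterior-network architecture and schedule.

    The reference recipe uses hidden width 1000 across the seven fully
    connected layers, batch size 100, learning rate 5e-5 and early stopping
    with 30-epoch patience on the validation loss (10% split).  ``desk()``
    narrows the hidden width and switches to Adam so the network trains in
    minutes on one CPU core; the architecture family is unchanged.
    """

    n_fibers: int = 1
    n_components: int = None  # defaults to default_n_components(n_fibers)
    hidden_width: int = 1000
    n_hidden_layers: int = 7
    dropout: float = 0.1
    optimizer: str = "sgd"
    learning_rate: float = 5e-5
    momentum: float = 0.0
    batch_size: int = 100
    epochs: int = 500
    patience: int = 30
    val_fraction: float = 0.1
    train_size: int = 2_000_000
    noise_sigma: float = 0.04
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_fibers not in (1, 2, 3):
            raise ValueError("n_fibers must be 1, 2 or 3")
        if self.n_components is None:
            object.__setattr__(self, "n_components",
                               default_n_components(self.n_fibers))
        if self.n_components < math.factorial(self.n_fibers):
            raise ValueError("need at least n! mixture components")

    @property
    def dim(self) -> int:
        return 6 * self.n_fibers

    @classmethod
    def desk(cls, n_fibers: int, train_size: int = 20_000,
             epochs: int = 15, seed: int = 0, noise_sigma: float = 0.04,
             ) -> "PosteriorNetConfig":
        return cls(n_fibers=n_fibers, hidden_width=256,
                   optimizer="adam", learning_rate=5e-4, epochs=epochs,
                   patience=epochs, train_size=train_size,
                   noise_sigma=noise_sigma, seed=seed)


def snpe_loss(head: MdnNll, raw: np.ndarray, alphas_std: np.ndarray,
              check_support: bool = True):
    """Single-round posterior-estimation loss and its head gradient.

    With the proposal equal to the prior, the importance ratio and the
    normalization constant are unity, so the loss is the negative mean log
    mixture density of the standardized αⱼ under q_ψ(· | yⱼ).
    """
    alphas_std = np.atleast_2d(alphas_std)
    if check_support and np.any(np.abs(alphas_std) > 0.5 + 1e-9):
        raise ValueError("α outside the prior box under the prior proposal")
    return head.loss_and_grad(raw, alphas_std)


def build_posterior_net(cfg: PosteriorNetConfig):
    """Conv trunk (classifier family) + seven fully connected layers whose
    final layer emits the mixture head of the declared (n, m)."""
    head = MdnNll(cfg.dim, cfg.n_components)
    rng = np.random.default_rng(cfg.seed)
    drop_rng = np.random.default_rng(cfg.seed + 7919)
    size = MAP_SHAPE[0]
    for _ in range(2):
        size = (size + 2 * 4 - 5 + 1) // 2
    flat = 6 * size * size
    layers = [
        Conv2d(MAP_SHAPE[2], 6, 5, 4, rng), ReLU(), MaxPool2d(),
        Conv2d(6, 6, 5, 4, rng), ReLU(), MaxPool2d(),
        Flatten(),
    ]
    w_in = flat
    for _ in range(cfg.n_hidden_layers - 1):
        layers += [Linear(w_in, cfg.hidden_width, rng), ReLU()]
        if cfg.dropout > 0:
            layers.append(Dropout(cfg.dropout, drop_rng))
        w_in = cfg.hidden_width
    layers.append(Linear(w_in, head.head_size, rng))
    return Sequential(*layers), head


@dataclass
class PosteriorModel:
    """Trained posterior network for a fixed fiber count."""

    net: Sequential
    head: MdnNll
    config: PosteriorNetConfig
    prior: PriorSpec
    trained: bool = False
    log: TrainLog = field(default_factory=TrainLog)
    run_config_hash: str = None  # pipeline-config provenance

    # -- standardization ----------------------------------------------------
    def _bounds(self):
        return self.prior.bounds(self.config.n_fibers)

    def standardize(self, alphas: np.ndarray) -> np.ndarray:
        lo, hi = self._bounds()
        return (np.asarray(alphas, dtype=float) - lo) / (hi - lo) - 0.5

    def unstandardize(self, z: np.ndarray) -> np.ndarray:
        lo, hi = self._bounds()
        return lo + (np.asarray(z, dtype=float) + 0.5) * (hi - lo)

    # -- inference ----------------------------------------------------------
    def raw_head(self, maps: np.ndarray) -> np.ndarray:
        x = np.asarray(maps, dtype=np.float32)
        if x.shape == MAP_SHAPE:
            x = x[None]
        return self.net.forward(x.transpose(0, 3, 1, 2), train=False)

    def posterior_for_map(self, odf_map: np.ndarray) -> MixturePosterior:
        """Mixture posterior in natural parameter units for one ODF map."""
        raw = self.raw_head(odf_map)
        weights, means_std, covs_std = self.head.mixture_moments(raw)
        lo, hi = self._bounds()
        scale = hi - lo
        means = lo + (means_std[0] + 0.5) * scale
        covs = covs_std[0] * np.outer(scale, scale)[None, :, :]
        return MixturePosterior(weights=weights[0], means=means, covs=covs)

    def log_density(self, maps: np.ndarray, alphas: np.ndarray) -> np.ndarray:
        """Per-voxel posterior log-density at natural-unit α (Jacobian of the
        standardization included, so values refer to natural units)."""
        raw = self.raw_head(maps)
        z = np.atleast_2d(self.standardize(alphas))
        lo, hi = self._bounds()
        log_jac = -np.log(hi - lo).sum()
        return self.head.log_density(raw, z) + log_jac

    def estimate(self, odf_map: np.ndarray, rule: str = "printed",
                 ) -> ParameterEstimate:
        post = self.posterior_for_map(odf_map)
        return select_dominant_component(post, rule=rule,
                                         prior_bounds=self._bounds())

    # -- persistence ---------------------------------------------------------
    def save(self, path, run_config_hash: str = None) -> None:
        with open(path, "wb") as fh:
            pickle.dump({"config": self.config, "prior": self.prior,
                         "state": self.net.state(),
                         "trained": self.trained,
                         "run_config_hash": run_config_hash
                         or self.run_config_hash}, fh)

    @classmethod
    def load(cls, path) -> "PosteriorModel":
        with open(path, "rb") as fh:
            blob = pickle.load(fh)
        net, head = build_posterior_net(blob["config"])
        net.load_state(blob["state"])
        return cls(net=net, head=head, config=blob["config"],
                   prior=blob["prior"], trained=blob["trained"],
                   run_config_hash=blob.get("run_config_hash"))


# --------------------------------------------------------------------------
# training data and loop
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SimulatedDataset:
    """Aligned (α, ODF map) pairs drawn from the prior via the simulator."""

    alphas: np.ndarray  # (N, 6n) natural units
    maps: np.ndarray  # (N, 32, 32, 3) float32
    n_fibers: int
    noise_sigma: float
    seed: int


def make_training_data(prior: PriorSpec, n_fibers: int, count: int,
                       renderer: MapRenderer, seed,
                       noise_sigma: float = None) -> SimulatedDataset:
    """Simulate a labeled training set: prior draw → signal → noise → map."""
    sigma = prior.noise_sigma if noise_sigma is None else noise_sigma
    rng = np.random.default_rng(seed)
    alphas = sample_prior_alphas(prior, n_fibers, count, rng)
    signals = simulate_signals(alphas, prior.w_fast, renderer.scheme)
    if sigma > 0:
        signals = signals + rng.normal(0.0, sigma, signals.shape)
    maps = renderer.render_batch(signals)
    return SimulatedDataset(alphas=alphas, maps=maps, n_fibers=n_fibers,
                            noise_sigma=sigma, seed=int(seed))


def train_posterior(cfg: PosteriorNetConfig, prior: PriorSpec,
                    renderer: MapRenderer,
                    dataset: SimulatedDataset = None) -> PosteriorModel:
    """Train a posterior network for cfg.n_fibers.

    The dataset is simulated from the prior unless one is supplied; early
    stopping monitors the validation loss with the configured patience and
    the best-validation parameters are restored at the end.
    """
    net, head = build_posterior_net(cfg)
    model = PosteriorModel(net=net, head=head, config=cfg, prior=prior)
    if dataset is None:
        dataset = make_training_data(prior, cfg.n_fibers, cfg.train_size,
                                     renderer, cfg.seed + 13,
                                     noise_sigma=cfg.noise_sigma)
    if dataset.alphas.shape[0] == 0:
        raise ValueError("empty training dataset")
    x = dataset.maps.transpose(0, 3, 1, 2).astype(np.float32)
    z = model.standardize(dataset.alphas)
    rng = np.random.default_rng(cfg.seed + 2)
    idx = rng.permutation(len(z))
    n_val = max(1, int(round(cfg.val_fraction * len(z))))
    val_idx, train_idx = idx[:n_val], idx[n_val:]
    opt = make_optimizer(cfg.optimizer, net.params(), cfg.learning_rate,
                         cfg.momentum)
    stopper = EarlyStopper(cfg.patience)
    for _ in range(cfg.epochs):
        tot = cnt = 0
        for batch in iterate_minibatches(len(train_idx), cfg.batch_size, rng):
            sel = train_idx[batch]
            raw = net.forward(x[sel], train=True)
            loss, grad = snpe_loss(head, raw, z[sel])
            if not np.isfinite(loss):
                raise FloatingPointError("posterior training loss diverged")
            net.backward(grad.astype(np.float32))
            opt.step()
            tot += loss * len(sel)
            cnt += len(sel)
        raw_val = net.forward(x[val_idx], train=False)
        val_loss, _ = snpe_loss(head, raw_val, z[val_idx])
        model.log.record(tot / cnt, val_loss)
        if stopper.update(val_loss, net):
            break
    stopper.restore(net)
    model.log.best_val = stopper.best
    model.log.best_epoch = int(np.argmin(model.log.val_loss))
    model.trained = True
    return model
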