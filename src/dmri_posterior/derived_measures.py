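"""Closed-form microstructure measures and unscented uncertainty propagation.

For the biexponential multi-tensor model the usual propagator summaries have
closed forms in the compartment eigenvalues (μm²/ms, fast fraction w):

* FA of the fast cylindrical tensor:  sqrt((λ1−λ2)² / (λ1² + 2λ2²))
* GFA of a signal shell:              std(S) / rms(S)
* MSD:   (1/n) π² Σᵢ [wᵢ(λ1ᵢ+2λ2ᵢ) + (1−wᵢ)(λ3ᵢ+2λ4ᵢ)]
* RTOP:  (2/n) π^{3/2} Σᵢ [wᵢ/(λ2ᵢ√λ1ᵢ) + (1−wᵢ)/(λ4ᵢ√λ3ᵢ)]
* MD of the fast tensor:              (λ1 + 2λ2)/3

The diffusion-time convention is absorbed into the π² and 2π^{3/2}
prefactors, so MSD/RTOP are comparable within this model convention only.
Posterior uncertainty is pushed through these nonlinear maps with the
standard symmetric sigma-point unscented transform (exact for affine maps).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.linalg import cholesky

__all__ = [
    "EigenvalueSet",
    "MeasureEstimate",
    "UtConfig",
    "fa_fast",
    "gfa",
    "gfa_of_signal",
    "msd",
    "rtop",
    "mean_diffusivity",
    "unscented_propagate",
    "variance_weighted_mean",
    "measure_from_eigenvalue_vector",
]


@dataclass(frozen=True)
class EigenvalueSet:
    """Per-fiber eigenvalue quadruples with a shared fast fraction."""

    lams: np.ndarray  # (n, 4): λ1..λ4 per fiber, μm²/ms
    w: float = 0.7

    def __post_init__(self) -> None:
        lams = np.atleast_2d(np.asarray(self.lams, dtype=float))
        if lams.shape[1] != 4:
            raise ValueError("expected four eigenvalues per fiber")
        if np.any(lams <= 0):
            raise ValueError("eigenvalues must be positive")
        if np.any(lams[:, 0] < lams[:, 1]) or np.any(lams[:, 2] < lams[:, 3]):
            raise ValueError("need λ1 ≥ λ2 and λ3 ≥ λ4 per fiber")
        object.__setattr__(self, "lams", lams)

    @property
    def n(self) -> int:
        return self.lams.shape[0]


@dataclass(frozen=True)
class MeasureEstimate:
    """Mean and standard deviation of one derived measure."""

    name: str
    mean: float
    std: float
    units: str = ""
    clipped_sigma_points: int = 0

    def __post_init__(self) -> None:
        if self.std < 0:
            raise ValueError("standard deviation must be non-negative")


def fa_fast(lam1, lam2):
    """FA of an axially symmetric tensor with eigenvalues (λ1, λ2, λ2)."""
    lam1 = np.asarray(lam1, dtype=float)
    lam2 = np.asarray(lam2, dtype=float)
    if np.any(lam1 < lam2) or np.any(lam2 <= 0):
        raise ValueError("need λ1 ≥ λ2 > 0")
    return np.sqrt((lam1 - lam2) ** 2 / (lam1**2 + 2.0 * lam2**2))


def gfa(signal_samples, *, population_std: bool = True):
    """Generalized FA of signal samples on one shell: std(S)/rms(S).

    Defaults to the population standard deviation (divide by N); with that
    convention GFA ∈ [0, 1] exactly since std² = rms² − mean².
    """
    s = np.asarray(signal_samples, dtype=float)
    if s.size < 2:
        raise ValueError("need at least two signal samples")
    rms = math.sqrt(float(np.mean(s**2)))
    if rms == 0:
        raise ValueError("all-zero signal has undefined GFA")
    std = float(np.std(s, ddof=0 if population_std else 1))
    return std / rms


def gfa_of_signal(signal, shell_id: int = 0, **kwargs):
    """GFA of a :class:`~dmri_posterior.forward_model.Signal` on one shell
    (default shell 0, i.e. b = 1000 s/mm² in the standard scheme)."""
    return gfa(signal.on_shell(shell_id), **kwargs)


def msd(ev: EigenvalueSet) -> float:
    """Mean squared displacement, μm² (model prefactor convention)."""
    lam = ev.lams
    per_fiber = (ev.w * (lam[:, 0] + 2.0 * lam[:, 1])
                 + (1.0 - ev.w) * (lam[:, 2] + 2.0 * lam[:, 3]))
    return float(math.pi**2 * per_fiber.mean())


def rtop(ev: EigenvalueSet) -> float:
    """Return-to-origin probability, model units.

    Compartment-wise inverse-root-determinant of the cylindrical tensor
    (det D = λ1 λ2² so 1/√det = 1/(λ2 √λ1)), with the 2π^{3/2} prefactor.
    """
    lam = ev.lams
    per_fiber = (ev.w / (lam[:, 1] * np.sqrt(lam[:, 0]))
                 + (1.0 - ev.w) / (lam[:, 3] * np.sqrt(lam[:, 2])))
    return float(2.0 * math.pi**1.5 * per_fiber.mean())


def mean_diffusivity(lam1, lam2):
    """MD of the fast cylindrical tensor: (λ1 + 2λ2)/3, μm²/ms."""
    lam1 = np.asarray(lam1, dtype=float)
    lam2 = np.asarray(lam2, dtype=float)
    if np.any(lam1 <= 0) or np.any(lam2 < 0):
        raise ValueError("eigenvalues must be positive")
    return (lam1 + 2.0 * lam2) / 3.0


def measure_from_eigenvalue_vector(name: str, w: float = 0.7):
    """Measure as a function of the flattened (n·4,) eigenvalue vector.

    The returned callable is what :func:`unscented_propagate` consumes when
    propagating the posterior of the eigenvalue sub-vector.
    """
    name = name.upper()

    def f(x: np.ndarray) -> float:
        lams = np.abs(np.asarray(x, dtype=float)).reshape(-1, 4)
        # enforce intra-tensor ordering so the measure stays defined on
        # sigma points that cross the λ1=λ2 boundary
        fast = np.sort(lams[:, :2], axis=1)[:, ::-1]
        slow = np.sort(lams[:, 2:], axis=1)[:, ::-1]
        ev = EigenvalueSet(lams=np.hstack([fast, slow]), w=w)
        if name == "FA":
            return float(np.mean(fa_fast(ev.lams[:, 0], ev.lams[:, 1])))
        if name == "MSD":
            return msd(ev)
        if name == "RTOP":
            return rtop(ev)
        if name == "MD":
            return float(np.mean(mean_diffusivity(ev.lams[:, 0],
                                                  ev.lams[:, 1])))
        raise ValueError(f"unknown measure '{name}'")

    return f


@dataclass(frozen=True)
class UtConfig:
    """Symmetric sigma-point set: 2d+1 points μ and μ ± √((d+κ)Σ) columns.

    ``kappa=None`` uses the classical κ = 3 − d; weights are κ/(d+κ) for the
    center and 1/(2(d+κ)) for the symmetric points, summing to one.
    """

    kappa: float = None
    eig_floor: float = 1e-6  # reflection floor for eigenvalue positivity


def _sigma_points(mean: np.ndarray, cov: np.ndarray, cfg: UtConfig):
    d = mean.size
    kappa = cfg.kappa if cfg.kappa is not None else 3.0 - d
    if d + kappa <= 0:
        raise ValueError("need d + κ > 0 for the sigma-point spread")
    try:
        root = cholesky((d + kappa) * cov, lower=True)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - scipy raises LinAlgError
        raise ValueError("covariance must be symmetric positive definite") from exc
    pts = np.vstack([mean[None, :],
                     mean[None, :] + root.T,
                     mean[None, :] - root.T])
    w0 = kappa / (d + kappa)
    wi = 1.0 / (2.0 * (d + kappa))
    weights = np.concatenate([[w0], np.full(2 * d, wi)])
    return pts, weights


_USE_CONFIG_FLOOR = object()


def unscented_propagate(mean, cov, f, cfg: UtConfig = None,
                        *, feasible_floor=_USE_CONFIG_FLOOR):
    """Propagate (mean, cov) through ``f`` with the unscented transform.

    Returns ``(mean_f, var_f, n_reflected)``.  Sigma points with entries
    below the feasible floor (default ``cfg.eig_floor``, guarding
    eigenvalue positivity) are reflected into the feasible region about the
    floor and counted; pass ``feasible_floor=None`` to disable reflection
    for unconstrained functions.
    """
    cfg = cfg or UtConfig()
    if feasible_floor is _USE_CONFIG_FLOOR:
        feasible_floor = cfg.eig_floor
    mean = np.asarray(mean, dtype=float).ravel()
    cov = np.atleast_2d(np.asarray(cov, dtype=float))
    if not np.allclose(cov, cov.T, atol=1e-10):
        raise ValueError("covariance must be symmetric")
    if np.any(np.abs(cov) > 0):
        pts, weights = _sigma_points(mean, cov, cfg)
    else:
        pts = mean[None, :]
        weights = np.array([1.0])
    n_reflected = 0
    floor = feasible_floor
    if floor is not None:
        below = pts < floor
        if np.any(below):
            n_reflected = int(np.any(below, axis=1).sum())
            pts = np.where(below, 2.0 * floor - pts, pts)
    vals = np.array([float(f(p)) for p in pts])
    mean_f = float(weights @ vals)
    var_f = float(weights @ (vals - mean_f) ** 2)
    return mean_f, max(var_f, 0.0), n_reflected


def propagate_measure(name: str, mean_lams, cov_lams, w: float = 0.7,
                      cfg: UtConfig = None) -> MeasureEstimate:
    """UT-propagated MeasureEstimate for one measure of one voxel."""
    f = measure_from_eigenvalue_vector(name, w=w)
    m, v, refl = unscented_propagate(mean_lams, cov_lams, f, cfg)
    units = {"FA": "", "MSD": "μm²", "RTOP": "model units",
             "MD": "μm²/ms"}.get(name.upper(), "")
    return MeasureEstimate(name=name.upper(), mean=m, std=math.sqrt(v),
                           units=units, clipped_sigma_points=refl)


def variance_weighted_mean(values, variances) -> float:
    """Inverse-variance weighted mean: Σ vᵢ/σᵢ² / Σ 1/σᵢ²."""
    v = np.asarray(values, dtype=float)
    s2 = np.asarray(variances, dtype=float)
    if v.shape != s2.shape or v.size == 0:
        raise ValueError("values and variances must align and be non-empty")
    if np.any(s2 <= 0):
        raise ValueError("variances must be strictly positive")
    wts = 1.0 / s2
    return float((v * wts).sum() / wts.sum())
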