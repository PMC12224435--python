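"""Biexponential multi-tensor forward model for multi-shell diffusion MRI.

Each fiber population is a pair of axially symmetric (cylindrical) Gaussian
compartments — a fast and a slow tensor sharing eigenvectors — mixed with a
fast-fraction ``w``.  A voxel holds 1–3 fiber populations; the normalized
attenuation along gradient direction ``u`` at b-value ``b`` is

    S(b, u) = (1/n) * sum_i [ w_i exp(-b uᵀD_i u) + (1-w_i) exp(-b uᵀD̄_i u) ]

with eigenvalues in μm²/ms and b in s/mm², so the exponent carries a factor
1e-3.  The 1/n normalization makes S(0, ·) = 1 for every fiber count.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "AcquisitionScheme",
    "FiberParams",
    "VoxelParams",
    "PriorSpec",
    "Signal",
    "spherical_to_unit",
    "unit_to_spherical",
    "orthonormal_completion",
    "tensor_from_fiber",
    "simulate_signal",
    "simulate_signals",
    "add_noise",
    "sample_prior",
    "count_equivalent_permutations",
    "crossing_angle_deg",
    "hcp_like_scheme",
]

#: unit conversion so that b [s/mm²] · λ [μm²/ms] becomes dimensionless
B_LAMBDA_SCALE = 1e-3


# --------------------------------------------------------------------------
# acquisition scheme
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class AcquisitionScheme:
    """Gradient directions with per-direction b-values.

    Directions are unit 3-vectors; shells group directions that share a
    b-value.  ``shell_ids`` is -1 for b=0 entries.
    """

    directions: np.ndarray  # (N, 3) unit vectors
    bvalues: np.ndarray  # (N,) s/mm²
    shell_ids: np.ndarray  # (N,) int, -1 for b=0

    def __post_init__(self) -> None:
        d = np.asarray(self.directions, dtype=float)
        b = np.asarray(self.bvalues, dtype=float)
        if d.ndim != 2 or d.shape[1] != 3 or d.shape[0] != b.shape[0]:
            raise ValueError("directions must be (N, 3) aligned with bvalues")
        norms = np.linalg.norm(d, axis=1)
        nonzero = b > 0
        if np.any(np.abs(norms[nonzero] - 1.0) > 1e-9):
            raise ValueError("gradient directions must be unit vectors")
        if np.any(b < 0):
            raise ValueError("b-values must be non-negative")
        object.__setattr__(self, "directions", d)
        object.__setattr__(self, "bvalues", b)
        object.__setattr__(self, "shell_ids", np.asarray(self.shell_ids, dtype=int))

    @classmethod
    def from_bvals_bvecs(cls, bvals, bvecs, *, shell_tolerance: float = 100.0,
                         nominal_shells=None) -> "AcquisitionScheme":
        """Build a scheme from FSL-style arrays (bvecs 3×N or N×3).

        Shells are assigned by nearest nominal b-value within
        ``shell_tolerance`` (real acquisitions jitter around nominal shells).
        """
        b = np.asarray(bvals, dtype=float).ravel()
        v = np.asarray(bvecs, dtype=float)
        if v.shape[0] == 3 and v.shape[1] != 3:
            v = v.T
        if v.shape != (b.size, 3):
            raise ValueError(
                f"bvecs shape {v.shape} does not match {b.size} bvals")
        v = v.copy()
        nz = b > shell_tolerance
        norms = np.linalg.norm(v[nz], axis=1)
        if np.any(norms == 0):
            raise ValueError("zero gradient vector on a diffusion-weighted volume")
        v[nz] /= norms[:, None]
        v[~nz] = 0.0
        if nominal_shells is None:
            nominal_shells = _infer_shells(b[nz], shell_tolerance)
        nominal_shells = np.sort(np.asarray(nominal_shells, dtype=float))
        sid = np.full(b.size, -1, dtype=int)
        for j in np.flatnonzero(nz):
            k = int(np.argmin(np.abs(nominal_shells - b[j])))
            if abs(nominal_shells[k] - b[j]) > shell_tolerance:
                raise ValueError(f"b={b[j]} matches no nominal shell")
            sid[j] = k
        # b=0 entries get a zero direction placeholder with unit norm to keep
        # the invariant trivial; they are flagged by shell_id == -1
        v[~nz] = np.array([1.0, 0.0, 0.0])
        return cls(directions=v, bvalues=b, shell_ids=sid)

    @property
    def n_measurements(self) -> int:
        return int(self.bvalues.size)

    @property
    def shells(self) -> np.ndarray:
        """Nominal b-value per shell id (mean of member b-values)."""
        ids = np.unique(self.shell_ids[self.shell_ids >= 0])
        return np.array([self.bvalues[self.shell_ids == i].mean() for i in ids])

    def shell_mask(self, shell_id: int) -> np.ndarray:
        return self.shell_ids == shell_id

    def to_bvals_bvecs(self):
        """Return (bvals (N,), bvecs (3, N)) in FSL text convention."""
        return self.bvalues.copy(), self.directions.T.copy()


def _infer_shells(b_nonzero: np.ndarray, tol: float) -> np.ndarray:
    shells: list[float] = []
    for val in np.sort(b_nonzero):
        if not shells or abs(val - shells[-1]) > tol:
            shells.append(float(val))
    return np.asarray(shells)


def fibonacci_hemisphere(n: int) -> np.ndarray:
    """n well-spread unit vectors on the upper hemisphere (golden spiral)."""
    i = np.arange(n) + 0.5
    z = i / n  # (0, 1): upper hemisphere
    phi = np.pi * (1.0 + math.sqrt(5.0)) * i
    r = np.sqrt(1.0 - z**2)
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def hcp_like_scheme(n_dirs_per_shell: int = 90,
                    shells=(1000.0, 2000.0, 3000.0),
                    n_b0: int = 0) -> AcquisitionScheme:
    """HCP-style multi-shell scheme: ``n_dirs_per_shell`` directions per shell.

    Synthetic pipelines work on normalized attenuations, so b=0 volumes are
    optional (``n_b0``) and mainly useful for NIfTI round-trip fixtures.
    """
    dirs = fibonacci_hemisphere(n_dirs_per_shell)
    all_dirs = [np.tile(np.array([[1.0, 0.0, 0.0]]), (n_b0, 1))]
    all_b = [np.zeros(n_b0)]
    all_sid = [np.full(n_b0, -1, dtype=int)]
    for k, b in enumerate(shells):
        all_dirs.append(dirs)
        all_b.append(np.full(n_dirs_per_shell, float(b)))
        all_sid.append(np.full(n_dirs_per_shell, k, dtype=int))
    return AcquisitionScheme(
        directions=np.vstack(all_dirs),
        bvalues=np.concatenate(all_b),
        shell_ids=np.concatenate(all_sid),
    )


# --------------------------------------------------------------------------
# model parameters
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class FiberParams:
    """One fiber population: orientation angles plus four eigenvalues.

    ``theta`` (polar) and ``phi`` (azimuth) are restricted to [0, π] — fiber
    orientations are axes (antipodally symmetric), so a hemisphere of the
    (θ, φ) parameterization covers them.  Eigenvalues are in μm²/ms with
    ``lam1 >= lam2`` (fast tensor) and ``lam3 >= lam4`` (slow tensor); ``w``
    is the fast-compartment fraction.
    """

    theta: float
    phi: float
    lam1: float
    lam2: float
    lam3: float
    lam4: float
    w: float = 0.7

    def __post_init__(self) -> None:
        if not (self.lam1 >= self.lam2 > 0 and self.lam3 >= self.lam4 > 0):
            raise ValueError(
                "eigenvalues must satisfy lam1 >= lam2 > 0 and lam3 >= lam4 > 0")
        if not (0.0 < self.w < 1.0):
            raise ValueError("fast fraction w must lie in (0, 1)")

    @property
    def direction(self) -> np.ndarray:
        return spherical_to_unit(self.theta, self.phi)

    def as_vector(self) -> np.ndarray:
        return np.array([self.theta, self.phi,
                         self.lam1, self.lam2, self.lam3, self.lam4])


@dataclass(frozen=True)
class VoxelParams:
    """Parameter vector α of a voxel: an ordered list of 1–3 fibers."""

    fibers: tuple

    def __post_init__(self) -> None:
        fibers = tuple(self.fibers)
        if not 1 <= len(fibers) <= 3:
            raise ValueError("a voxel holds between 1 and 3 fiber populations")
        object.__setattr__(self, "fibers", fibers)

    @property
    def n(self) -> int:
        return len(self.fibers)

    def as_vector(self) -> np.ndarray:
        """Flattened α of length 6n: [θ, φ, λ1..λ4] per fiber."""
        return np.concatenate([f.as_vector() for f in self.fibers])

    @property
    def weights(self) -> np.ndarray:
        return np.array([f.w for f in self.fibers])

    @classmethod
    def from_vector(cls, alpha, w: float = 0.7) -> "VoxelParams":
        alpha = np.asarray(alpha, dtype=float).ravel()
        if alpha.size % 6 != 0:
            raise ValueError("α length must be a multiple of 6")
        fibers = [FiberParams(*alpha[6 * i:6 * i + 6], w=w)
                  for i in range(alpha.size // 6)]
        return cls(fibers=tuple(fibers))

    def permuted(self, order) -> "VoxelParams":
        return VoxelParams(fibers=tuple(self.fibers[i] for i in order))


@dataclass(frozen=True)
class Signal:
    """Normalized diffusion attenuation, one value per scheme measurement."""

    values: np.ndarray
    scheme: AcquisitionScheme

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (self.scheme.n_measurements,):
            raise ValueError("signal length does not match the scheme")
        object.__setattr__(self, "values", v)

    def on_shell(self, shell_id: int) -> np.ndarray:
        return self.values[self.scheme.shell_mask(shell_id)]


# --------------------------------------------------------------------------
# geometry helpers
# --------------------------------------------------------------------------

def spherical_to_unit(theta, phi) -> np.ndarray:
    """m(θ, φ) = (sinθ cosφ, sinθ sinφ, cosθ); broadcasts over arrays."""
    theta = np.asarray(theta, dtype=float)
    phi = np.asarray(phi, dtype=float)
    st = np.sin(theta)
    return np.stack([st * np.cos(phi), st * np.sin(phi), np.cos(theta)],
                    axis=-1)


def unit_to_spherical(m) -> tuple:
    """Inverse of :func:`spherical_to_unit`, folded so θ, φ ∈ [0, π].

    The fold uses antipodal symmetry: if φ lands outside [0, π], the axis is
    negated first.
    """
    m = np.asarray(m, dtype=float)
    m = m / np.linalg.norm(m)
    phi = math.atan2(m[1], m[0])
    if phi < 0 or phi > math.pi:
        m = -m
        phi = math.atan2(m[1], m[0])
    if phi < 0:  # atan2 returns (-π, π]; negation of φ ∈ (π, π] edge case
        phi += math.pi
        m = m.copy()
    theta = math.acos(np.clip(m[2], -1.0, 1.0))
    return theta, phi


def orthonormal_completion(m: np.ndarray) -> tuple:
    """Deterministic orthonormal pair (p, v) completing axis ``m``.

    Built from a fixed reference axis (z, with an x fallback when ``m`` is
    within ~25° of z).  Any completion gives the same cylindrical tensor, so
    downstream results do not depend on this choice.
    """
    m = np.asarray(m, dtype=float)
    ref = np.array([0.0, 0.0, 1.0])
    if abs(np.dot(m, ref)) > 0.9:
        ref = np.array([1.0, 0.0, 0.0])
    p = ref - np.dot(ref, m) * m
    p /= np.linalg.norm(p)
    v = np.cross(m, p)
    return p, v


def crossing_angle_deg(m1, m2) -> float:
    """Angle between two fiber axes, folded into [0°, 90°]."""
    c = abs(float(np.clip(np.dot(m1, m2), -1.0, 1.0)))
    return math.degrees(math.acos(min(c, 1.0)))


# --------------------------------------------------------------------------
# forward model
# --------------------------------------------------------------------------

def tensor_from_fiber(f: FiberParams) -> tuple:
    """Fast and slow cylindrical tensors (D, D̄) of one fiber, μm²/ms.

    D = λ1 mmᵀ + λ2 (ppᵀ + vvᵀ) = λ2 I + (λ1 − λ2) mmᵀ, so the result is
    independent of the orthonormal completion (p, v).
    """
    m = f.direction
    eye = np.eye(3)
    mm = np.outer(m, m)
    d_fast = f.lam2 * eye + (f.lam1 - f.lam2) * mm
    d_slow = f.lam4 * eye + (f.lam3 - f.lam4) * mm
    return d_fast, d_slow


def simulate_signal(vp: VoxelParams, scheme: AcquisitionScheme) -> Signal:
    """Noiseless attenuation of one voxel on the given scheme."""
    values = _attenuation(
        vp.as_vector()[None, :], vp.weights[None, :], scheme)[0]
    return Signal(values=values, scheme=scheme)


def simulate_signals(alphas: np.ndarray, weights, scheme: AcquisitionScheme,
                     ) -> np.ndarray:
    """Vectorized attenuation for a batch of α vectors.

    Parameters
    ----------
    alphas : (B, 6n) array of flattened parameter vectors.
    weights : scalar, (n,) or (B, n) fast fractions.
    """
    alphas = np.asarray(alphas, dtype=float)
    if alphas.ndim != 2 or alphas.shape[1] % 6 != 0:
        raise ValueError("alphas must be (B, 6n)")
    n = alphas.shape[1] // 6
    w = np.broadcast_to(np.asarray(weights, dtype=float),
                        (alphas.shape[0], n))
    return _attenuation(alphas, w, scheme)


def _attenuation(alphas: np.ndarray, w: np.ndarray,
                 scheme: AcquisitionScheme) -> np.ndarray:
    b = scheme.bvalues[None, None, :] * B_LAMBDA_SCALE  # (1, 1, N)
    u = scheme.directions  # (N, 3)
    n = alphas.shape[1] // 6
    p = alphas.reshape(alphas.shape[0], n, 6)  # (B, n, 6)
    m = spherical_to_unit(p[..., 0], p[..., 1])  # (B, n, 3)
    c2 = (m @ u.T) ** 2  # (B, n, N) squared cosines
    lam1, lam2 = p[..., 2, None], p[..., 3, None]
    lam3, lam4 = p[..., 4, None], p[..., 5, None]
    # uᵀDu = λ2 + (λ1−λ2) (u·m)² for a cylindrical tensor
    q_fast = lam2 + (lam1 - lam2) * c2
    q_slow = lam4 + (lam3 - lam4) * c2
    s = (w[..., None] * np.exp(-b * q_fast)
         + (1.0 - w[..., None]) * np.exp(-b * q_slow))
    # sort per-fiber contributions before averaging so that permuting the
    # fiber blocks yields a bit-identical signal (fixed summation order)
    return np.sort(s, axis=1).mean(axis=1)  # 1/n normalization


def add_noise(s: Signal, sigma: float, seed) -> Signal:
    """Add i.i.d. zero-mean Gaussian noise; reproducible under ``seed``."""
    if sigma < 0:
        raise ValueError("noise sigma must be non-negative")
    if sigma == 0:
        return s
    rng = np.random.default_rng(seed)
    return replace(s, values=s.values + rng.normal(0.0, sigma, s.values.shape))


def count_equivalent_permutations(n: int, scheme: AcquisitionScheme = None,
                                  seed: int = 0) -> int:
    """Number of fiber-block orderings of α that yield the identical signal.

    Verified constructively: a random n-fiber voxel is simulated under every
    permutation of its fiber blocks and the signals compared bit-wise.
    """
    if n not in (1, 2, 3):
        raise ValueError("fiber count must be 1, 2 or 3")
    if scheme is None:
        scheme = hcp_like_scheme(30)
    vps = sample_prior(PriorSpec(), n, 1, seed)
    vp = vps[0]
    ref = simulate_signal(vp, scheme).values
    count = 0
    for order in itertools.permutations(range(n)):
        sig = simulate_signal(vp.permuted(order), scheme).values
        if np.array_equal(sig, ref):
            count += 1
    return count


# --------------------------------------------------------------------------
# prior
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PriorSpec:
    """Uniform box prior over α with rejection constraints.

    Defaults follow the training configuration: fast eigenvalues uniform on
    [1, 3] μm²/ms with λ1 ≥ λ2, slow eigenvalues on [0.1, 0.6] with λ3 ≥ λ4,
    fast fraction fixed at 0.7, θ, φ uniform on [0, π].  Multi-fiber draws
    additionally require fast-component FA > 0.2 and a minimum pairwise
    crossing angle (10° for two fibers with a 90° cap, 45° for three).
    """

    theta_range: tuple = (0.0, math.pi)
    phi_range: tuple = (0.0, math.pi)
    lam_fast_range: tuple = (1.0, 3.0)
    lam_slow_range: tuple = (0.1, 0.6)
    w_fast: float = 0.7
    min_fa_multi: float = 0.2
    min_angle_deg: dict = field(
        default_factory=lambda: {1: 0.0, 2: 10.0, 3: 45.0})
    max_angle_deg: dict = field(
        default_factory=lambda: {1: 180.0, 2: 90.0, 3: 180.0})
    noise_sigma: float = 0.04

    def bounds(self, n: int) -> tuple:
        """(lo, hi) arrays of length 6n for the flattened α."""
        lo = np.tile([self.theta_range[0], self.phi_range[0],
                      self.lam_fast_range[0], self.lam_fast_range[0],
                      self.lam_slow_range[0], self.lam_slow_range[0]], n)
        hi = np.tile([self.theta_range[1], self.phi_range[1],
                      self.lam_fast_range[1], self.lam_fast_range[1],
                      self.lam_slow_range[1], self.lam_slow_range[1]], n)
        return lo, hi


def _fa_axial(lam1, lam2):
    num = (lam1 - lam2) ** 2
    den = lam1**2 + 2.0 * lam2**2
    return np.sqrt(num / den)


def sample_prior(spec: PriorSpec, n_fibers: int, count: int, seed,
                 *, max_reject_rounds: int = 200) -> list:
    """Draw ``count`` VoxelParams uniformly on the constrained prior.

    Uses rejection sampling, which is exactly uniform on the constrained
    set: eigenvalue ordering comes free from sorting two i.i.d. uniforms,
    the FA floor (multi-fiber only) and the crossing-angle window are
    enforced by rejection.
    """
    if n_fibers not in (1, 2, 3):
        raise ValueError("n_fibers must be 1, 2 or 3")
    if count < 1:
        raise ValueError("count must be positive")
    rng = np.random.default_rng(seed)
    alphas = sample_prior_alphas(spec, n_fibers, count, rng,
                                 max_reject_rounds=max_reject_rounds)
    return [VoxelParams.from_vector(a, w=spec.w_fast) for a in alphas]


def sample_prior_alphas(spec: PriorSpec, n_fibers: int, count: int, rng,
                        *, max_reject_rounds: int = 200) -> np.ndarray:
    """Vectorized prior sampler returning a (count, 6n) array of α."""
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    out = np.empty((count, 6 * n_fibers))
    filled = 0
    drawn = accepted = 0
    for _ in range(max_reject_rounds):
        need = count - filled
        # size batches by the running acceptance estimate so low-acceptance
        # constraint sets still fill in a handful of rounds
        rate = accepted / drawn if drawn else 1.0
        batch = int(min(max(1.5 * need / max(rate, 1e-3), 2 * need, 64),
                        2_000_000))
        cand = _draw_batch(spec, n_fibers, batch, rng)
        ok = _constraints_ok(spec, n_fibers, cand)
        drawn += batch
        accepted += int(ok.sum())
        good = cand[ok][:need]
        out[filled:filled + good.shape[0]] = good
        filled += good.shape[0]
        if filled == count:
            return out
        if drawn >= 10_000 and accepted / drawn < 1e-3:
            break
    raise RuntimeError(
        "prior rejection rate exceeds 99.9%; constraint combination infeasible")


def _draw_batch(spec: PriorSpec, n: int, batch: int, rng) -> np.ndarray:
    th = rng.uniform(*spec.theta_range, (batch, n))
    ph = rng.uniform(*spec.phi_range, (batch, n))
    fast = np.sort(rng.uniform(*spec.lam_fast_range, (batch, n, 2)), axis=-1)
    slow = np.sort(rng.uniform(*spec.lam_slow_range, (batch, n, 2)), axis=-1)
    cand = np.empty((batch, n, 6))
    cand[..., 0] = th
    cand[..., 1] = ph
    cand[..., 2] = fast[..., 1]  # λ1 ≥ λ2
    cand[..., 3] = fast[..., 0]
    cand[..., 4] = slow[..., 1]  # λ3 ≥ λ4
    cand[..., 5] = slow[..., 0]
    return cand.reshape(batch, 6 * n)


def _constraints_ok(spec: PriorSpec, n: int, cand: np.ndarray) -> np.ndarray:
    ok = np.ones(cand.shape[0], dtype=bool)
    p = cand.reshape(cand.shape[0], n, 6)
    if n >= 2:
        fa = _fa_axial(p[..., 2], p[..., 3])
        ok &= np.all(fa > spec.min_fa_multi, axis=1)
        m = spherical_to_unit(p[..., 0], p[..., 1])  # (B, n, 3)
        lo = math.cos(math.radians(spec.min_angle_deg.get(n, 0.0)))
        hi = math.cos(math.radians(min(spec.max_angle_deg.get(n, 180.0), 90.0)))
        for i, j in itertools.combinations(range(n), 2):
            c = np.abs(np.einsum("bk,bk->b", m[:, i], m[:, j])).clip(0, 1)
            ok &= (c <= lo + 1e-12) & (c >= hi - 1e-12)
    return ok
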