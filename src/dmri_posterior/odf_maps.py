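"""Spherical-harmonic ODF estimation and the 2D ODF-map representation.

Per b-shell, the signal is fit with the real, symmetric (even-order)
spherical-harmonic basis by regularized least squares; the analytic q-ball
diffusion ODF follows by scaling each degree-l coefficient with its
Funk–Radon eigenvalue 2π P_l(0).  Evaluating the three per-shell ODFs on a
uniform 32×32 (θ, φ) grid and min–max normalizing each channel yields the
32×32×3 map consumed by the classifier and posterior networks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import sph_harm_y

from .forward_model import AcquisitionScheme, Signal, fibonacci_hemisphere

__all__ = [
    "ShCoefficients",
    "OdfMap",
    "PeakSet",
    "sh_basis_size",
    "real_sym_sh_basis",
    "fit_sh",
    "ShellFitter",
    "compute_odf",
    "evaluate_sh",
    "render_map",
    "render_maps_batch",
    "find_peaks",
    "MAP_SHAPE",
]

MAP_SHAPE = (32, 32, 3)


def sh_basis_size(order: int) -> int:
    """Number of real symmetric SH basis functions up to even order L.

    Counts (l, m) with l even, 0 ≤ l ≤ L, |m| ≤ l: (L+1)(L+2)/2.
    """
    if order < 0 or order % 2 != 0:
        raise ValueError("SH order must be even and non-negative")
    return (order + 1) * (order + 2) // 2


def sh_degrees(order: int) -> np.ndarray:
    """Degree l of each basis function, in basis order."""
    out = []
    for l in range(0, order + 1, 2):
        out.extend([l] * (2 * l + 1))
    return np.asarray(out, dtype=int)


def real_sym_sh_basis(order: int, theta, phi) -> np.ndarray:
    """Design matrix of the real symmetric SH basis at points (θ, φ).

    Ordering is (l, m) with l = 0, 2, ..., L and m = -l..l; the m < 0 entries
    are √2·(-1)^m·Im(Y_l^{|m|}), m = 0 is Y_l^0, and m > 0 entries are
    √2·(-1)^m·Re(Y_l^m) (the convention common in q-ball work).  θ is the
    polar angle.
    """
    theta = np.atleast_1d(np.asarray(theta, dtype=float))
    phi = np.atleast_1d(np.asarray(phi, dtype=float))
    n = theta.size
    cols = []
    for l in range(0, order + 1, 2):
        for m in range(-l, l + 1):
            am = abs(m)
            y = sph_harm_y(l, am, theta, phi)
            sign = (-1.0) ** am
            if m < 0:
                cols.append(math.sqrt(2.0) * sign * y.imag)
            elif m == 0:
                cols.append(y.real)
            else:
                cols.append(math.sqrt(2.0) * sign * y.real)
    return np.stack(cols, axis=-1).reshape(n, -1)


@dataclass(frozen=True)
class ShCoefficients:
    """Real symmetric SH coefficients of one shell's signal or ODF."""

    order: int
    coeffs: np.ndarray
    shell_id: int = 0

    def __post_init__(self) -> None:
        c = np.asarray(self.coeffs, dtype=float)
        if c.shape != (sh_basis_size(self.order),):
            raise ValueError(
                f"expected {sh_basis_size(self.order)} coefficients for "
                f"order {self.order}, got {c.shape}")
        object.__setattr__(self, "coeffs", c)


class ShellFitter:
    """Precomputed regularized least-squares SH fit for one direction set.

    The Laplace–Beltrami penalty weights coefficient j by (l_j(l_j+1))²,
    damping high-degree terms under noise; ``reg=0`` gives the plain
    pseudo-inverse (exact in the band-limited regime).
    """

    def __init__(self, directions: np.ndarray, order: int,
                 reg: float = 6e-3) -> None:
        d = np.asarray(directions, dtype=float)
        theta = np.arccos(np.clip(d[:, 2], -1.0, 1.0))
        phi = np.arctan2(d[:, 1], d[:, 0])
        nb = sh_basis_size(order)
        if d.shape[0] < nb:
            raise ValueError(
                f"{d.shape[0]} directions under-determine an order-{order} "
                f"fit ({nb} coefficients)")
        self.order = order
        self.basis = real_sym_sh_basis(order, theta, phi)  # (N, nb)
        l = sh_degrees(order).astype(float)
        lb = np.diag((l * (l + 1.0)) ** 2)
        gram = self.basis.T @ self.basis + reg * lb
        self._solve = np.linalg.solve(gram, self.basis.T)  # (nb, N)

    def fit(self, values: np.ndarray) -> np.ndarray:
        """Coefficients for one signal (N,) or a batch (B, N) → (..., nb)."""
        return np.asarray(values, dtype=float) @ self._solve.T


def fit_sh(signal: Signal, shell_id: int, order: int,
           reg: float = 6e-3) -> ShCoefficients:
    """Fit SH coefficients to the signal restricted to one shell."""
    mask = signal.scheme.shell_mask(shell_id)
    fitter = ShellFitter(signal.scheme.directions[mask], order, reg)
    return ShCoefficients(order=order, coeffs=fitter.fit(signal.values[mask]),
                          shell_id=shell_id)


def legendre_at_zero(l: int) -> float:
    """P_l(0) = (-1)^{l/2} (l-1)!! / l!! for even l, 0 for odd l."""
    if l % 2 == 1:
        return 0.0
    if l == 0:
        return 1.0
    k = l // 2
    return (-1.0) ** k * math.prod(range(1, l, 2)) / math.prod(range(2, l + 1, 2))


def funk_radon_eigenvalues(order: int) -> np.ndarray:
    """Per-coefficient Funk–Radon eigenvalue 2π P_l(0), in basis order."""
    return np.array([2.0 * math.pi * legendre_at_zero(l)
                     for l in sh_degrees(order)])


def compute_odf(c: ShCoefficients) -> ShCoefficients:
    """Analytic q-ball ODF from signal SH coefficients (Funk–Radon scaling)."""
    return ShCoefficients(order=c.order,
                          coeffs=c.coeffs * funk_radon_eigenvalues(c.order),
                          shell_id=c.shell_id)


def _m0_column_indices(order: int) -> list:
    cols, idx = [], 0
    for l in range(0, order + 1, 2):
        cols.append(idx + l)
        idx += 2 * l + 1
    return cols


def single_fiber_response(bvalue: float, order: int,
                          lam_fast=(3.0, 1.0), lam_slow=(0.5, 0.2),
                          w: float = 0.7) -> np.ndarray:
    """Per-degree rotational harmonics of a canonical single-fiber ODF.

    The response is the q-ball ODF of one high-anisotropy biexponential
    fiber aligned with z; only m=0 coefficients are non-zero, and the
    spherical convolution factor per degree l is √(4π/(2l+1))·r_l0,
    normalized so degree 0 has factor 1.  Used to sharpen multi-fiber ODFs
    by per-degree deconvolution.
    """
    theta = np.linspace(0.0, math.pi, 1024)
    c2 = np.cos(theta) ** 2
    b = bvalue * 1e-3
    lam1, lam2 = lam_fast
    lam3, lam4 = lam_slow
    s = (w * np.exp(-b * (lam2 + (lam1 - lam2) * c2))
         + (1.0 - w) * np.exp(-b * (lam4 + (lam3 - lam4) * c2)))
    basis = real_sym_sh_basis(order, theta, np.zeros_like(theta))
    a = basis[:, _m0_column_indices(order)]
    wts = np.sqrt(np.sin(theta) + 1e-9)  # area weighting on the ring grid
    coeffs, *_ = np.linalg.lstsq(a * wts[:, None], s * wts, rcond=None)
    frt = np.array([2.0 * math.pi * legendre_at_zero(l)
                    for l in range(0, order + 1, 2)])
    ls = np.arange(0, order + 1, 2)
    conv = np.sqrt(4.0 * math.pi / (2 * ls + 1)) * coeffs * frt
    return conv / conv[0]


def sharpening_gains(conv: np.ndarray, order: int,
                     tau_rel: float = 0.05) -> np.ndarray:
    """Per-coefficient deconvolution gain k_l/(k_l² + τ²), τ = tau_rel·|k_2|.

    τ = 0 gives exact deconvolution (noise-amplifying); the default mildly
    damps the near-null high degrees under measurement noise.
    """
    tau = tau_rel * abs(conv[1]) if len(conv) > 1 else 0.0
    per_degree = {2 * i: (k / (k * k + tau * tau) if tau > 0 else 1.0 / k)
                  for i, k in enumerate(conv)}
    return np.array([per_degree[l] for l in sh_degrees(order)])


def sharpen_odf(c: ShCoefficients, bvalue: float,
                tau_rel: float = 0.05) -> ShCoefficients:
    """Deconvolution-sharpened ODF (fODF-like) for one shell."""
    conv = single_fiber_response(bvalue, c.order)
    return ShCoefficients(order=c.order,
                          coeffs=c.coeffs * sharpening_gains(conv, c.order,
                                                             tau_rel),
                          shell_id=c.shell_id)


def evaluate_sh(c: ShCoefficients, theta, phi) -> np.ndarray:
    """Evaluate the SH expansion at points (θ, φ)."""
    return real_sym_sh_basis(c.order, theta, phi) @ c.coeffs


@dataclass(frozen=True)
class OdfMap:
    """32×32×3 ODF image: rows ↦ θ ∈ [0, π], cols ↦ φ ∈ [0, 2π), one channel
    per b-shell (1000, 2000, 3000 s/mm²), each min–max normalized to [0, 1].
    A constant channel maps to all zeros under the min–max rule.
    """

    grid: np.ndarray

    def __post_init__(self) -> None:
        g = np.asarray(self.grid, dtype=np.float32)
        if g.shape != MAP_SHAPE:
            raise ValueError(f"ODF map must have shape {MAP_SHAPE}")
        if not np.all(np.isfinite(g)) or g.min() < 0 or g.max() > 1 + 1e-6:
            raise ValueError("ODF map values must be finite and in [0, 1]")
        object.__setattr__(self, "grid", g)


def map_grid(n_theta: int = 32, n_phi: int = 32) -> tuple:
    """Cell-centered (θ, φ) grid over [0, π] × [0, 2π)."""
    theta = (np.arange(n_theta) + 0.5) * math.pi / n_theta
    phi = np.arange(n_phi) * 2.0 * math.pi / n_phi
    return np.meshgrid(theta, phi, indexing="ij")


def _minmax(channel: np.ndarray) -> np.ndarray:
    lo, hi = channel.min(), channel.max()
    if hi - lo < 1e-12:
        return np.zeros_like(channel)
    return (channel - lo) / (hi - lo)


def render_map(odfs) -> OdfMap:
    """Render a 32×32×3 map from the three per-shell ODF expansions."""
    odfs = list(odfs)
    if len(odfs) != MAP_SHAPE[2]:
        raise ValueError(f"expected {MAP_SHAPE[2]} per-shell ODFs")
    tt, pp = map_grid()
    chans = []
    for c in odfs:
        vals = evaluate_sh(c, tt.ravel(), pp.ravel()).reshape(tt.shape)
        chans.append(_minmax(vals))
    return OdfMap(grid=np.stack(chans, axis=-1).astype(np.float32))


class MapRenderer:
    """Batched signal → ODF-map pipeline for one acquisition scheme.

    Precomputes, per shell, the SH fit operator, the Funk–Radon scaling and
    the grid evaluation matrix, so a batch of signals becomes three matrix
    products.  The output is identical to the per-voxel
    :func:`fit_sh` → :func:`compute_odf` → :func:`render_map` path.
    """

    def __init__(self, scheme: AcquisitionScheme, order: int = 8,
                 reg: float = 6e-3, sharpen: bool = True,
                 tau_rel: float = 0.05) -> None:
        self.scheme = scheme
        self.order = order
        self.sharpen = sharpen
        tt, pp = map_grid()
        grid_basis = real_sym_sh_basis(order, tt.ravel(), pp.ravel())
        frt = funk_radon_eigenvalues(order)
        self._ops = []
        shell_ids = np.unique(scheme.shell_ids[scheme.shell_ids >= 0])
        if shell_ids.size != MAP_SHAPE[2]:
            raise ValueError(
                f"scheme must have {MAP_SHAPE[2]} shells, found {shell_ids.size}")
        for sid in shell_ids:
            mask = scheme.shell_mask(int(sid))
            fitter = ShellFitter(scheme.directions[mask], order, reg)
            gains = frt.copy()
            if sharpen:
                b_nom = float(scheme.bvalues[mask].mean())
                conv = single_fiber_response(b_nom, order)
                gains = gains * sharpening_gains(conv, order, tau_rel)
            # signal (B, N_shell) -> grid values (B, 1024)
            op = fitter._solve.T * gains[None, :] @ grid_basis.T
            self._ops.append((mask, op))

    def render_batch(self, signals: np.ndarray) -> np.ndarray:
        """(B, N) signals → (B, 32, 32, 3) float32 normalized maps."""
        signals = np.atleast_2d(np.asarray(signals, dtype=float))
        b = signals.shape[0]
        out = np.empty((b, *MAP_SHAPE), dtype=np.float32)
        for k, (mask, op) in enumerate(self._ops):
            vals = (signals[:, mask] @ op).reshape(b, *MAP_SHAPE[:2])
            lo = vals.min(axis=(1, 2), keepdims=True)
            hi = vals.max(axis=(1, 2), keepdims=True)
            rng = hi - lo
            flat = rng < 1e-12
            rng[flat] = 1.0
            norm = (vals - lo) / rng
            norm[flat[:, 0, 0]] = 0.0
            out[..., k] = norm
        return out


def render_maps_batch(signals: np.ndarray, scheme: AcquisitionScheme,
                      order: int = 8, reg: float = 6e-3) -> np.ndarray:
    """Convenience wrapper building a :class:`MapRenderer` once."""
    return MapRenderer(scheme, order, reg).render_batch(signals)


# --------------------------------------------------------------------------
# peak finding
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PeakSet:
    """ODF maxima as unit axes folded into the θ, φ ∈ [0, π] hemisphere,
    sorted by descending amplitude."""

    directions: np.ndarray  # (k, 3)
    amplitudes: np.ndarray  # (k,)

    @property
    def n_peaks(self) -> int:
        return int(self.amplitudes.size)


def find_peaks(odf: ShCoefficients, min_separation_deg: float = 15.0,
               relative_threshold: float = 0.3,
               n_seeds: int = 1000) -> PeakSet:
    """Hill-climbing peak extraction on the ODF sphere.

    Seeds a dense hemisphere point set, ascends each seed with Nelder–Mead on
    the negative SH expansion, merges converged maxima closer than
    ``min_separation_deg`` (after antipodal folding) and drops peaks below
    ``relative_threshold`` × the global maximum above the ODF minimum.
    """
    if not (0.0 < relative_threshold <= 1.0) or min_separation_deg <= 0:
        raise ValueError("invalid peak thresholds")
    from scipy.optimize import minimize

    seeds = fibonacci_hemisphere(n_seeds)
    theta = np.arccos(np.clip(seeds[:, 2], -1, 1))
    phi = np.arctan2(seeds[:, 1], seeds[:, 0])
    vals = evaluate_sh(odf, theta, phi)
    floor, ceil = float(vals.min()), float(vals.max())
    if ceil - floor < 1e-12:
        return PeakSet(directions=np.empty((0, 3)), amplitudes=np.empty(0))
    cut = floor + relative_threshold * (ceil - floor)
    # keep strongest seeds; local ascent refines them to true maxima
    cand_idx = np.argsort(vals)[::-1][:64]
    cand_idx = cand_idx[vals[cand_idx] >= cut]

    def neg(x):
        return -float(evaluate_sh(odf, x[0], x[1])[0])

    found_dirs: list[np.ndarray] = []
    found_amps: list[float] = []
    merge_cos = math.cos(math.radians(min_separation_deg))
    for i in cand_idx:
        res = minimize(neg, x0=[theta[i], phi[i]], method="Nelder-Mead",
                       options={"xatol": 1e-4, "fatol": 1e-10, "maxiter": 200})
        amp = -res.fun
        if amp < cut:
            continue
        st = math.sin(res.x[0])
        d = np.array([st * math.cos(res.x[1]), st * math.sin(res.x[1]),
                      math.cos(res.x[0])])
        d /= np.linalg.norm(d)
        if d[2] < 0:  # fold antipodes into the upper hemisphere
            d = -d
        merged = False
        for k, prev in enumerate(found_dirs):
            if abs(float(np.dot(prev, d))) >= merge_cos:
                if amp > found_amps[k]:
                    found_dirs[k], found_amps[k] = d, amp
                merged = True
                break
        if not merged:
            found_dirs.append(d)
            found_amps.append(amp)
    if not found_dirs:
        return PeakSet(directions=np.empty((0, 3)), amplitudes=np.empty(0))
    amps = np.asarray(found_amps)
    order = np.argsort(amps)[::-1]
    keep = amps[order] >= relative_threshold * amps.max()
    order = order[keep]
    return PeakSet(directions=np.asarray(found_dirs)[order],
                   amplitudes=amps[order])
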