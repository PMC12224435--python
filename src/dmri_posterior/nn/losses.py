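"""Loss heads: softmax cross-entropy and the full-covariance MDN NLL.

The mixture head parameterizes each Gaussian component by the Cholesky
factor of its *precision* matrix (lower triangular, diagonal through exp),
which guarantees a symmetric positive-definite covariance for any finite
raw network output and yields simple analytic gradients of the negative
log-likelihood.
"""

from __future__ import annotations

import numpy as np

LOG_2PI = float(np.log(2.0 * np.pi))
_DIAG_CLIP = 8.0  # raw log-diagonal clip keeps precisions in exp(±8)


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray):
    """Mean cross-entropy over the batch and its gradient w.r.t. logits."""
    p = softmax(logits.astype(np.float64))
    b = logits.shape[0]
    nll = -np.log(np.clip(p[np.arange(b), labels], 1e-300, None))
    grad = p.copy()
    grad[np.arange(b), labels] -= 1.0
    return float(nll.mean()), (grad / b).astype(logits.dtype)


class MdnNll:
    """Negative mean log-likelihood of a full-covariance Gaussian mixture.

    The raw head vector per sample is laid out as
    ``[weight logits (m) | means (m·d) | log precision diagonals (m·d) |
    precision off-diagonals (m·d(d-1)/2)]``.
    """

    def __init__(self, n_dim: int, n_components: int) -> None:
        self.d = int(n_dim)
        self.m = int(n_components)
        self._tril = np.tril_indices(self.d, k=-1)

    @property
    def head_size(self) -> int:
        d, m = self.d, self.m
        return m * (1 + d + d + d * (d - 1) // 2)

    # -- raw head -> mixture parameters ------------------------------------
    def split(self, raw: np.ndarray):
        """(B, H) raw head → (logits (B,m), means (B,m,d), chol (B,m,d,d)).

        ``chol`` is the lower-triangular precision factor C with
        Λ = C Cᵀ and covariance Σ = Λ⁻¹.
        """
        raw = np.atleast_2d(np.asarray(raw, dtype=np.float64))
        if raw.shape[1] != self.head_size:
            raise ValueError(
                f"raw head width {raw.shape[1]} != expected {self.head_size}")
        if not np.all(np.isfinite(raw)):
            raise ValueError("non-finite network head output")
        b, d, m = raw.shape[0], self.d, self.m
        i = 0
        logits = raw[:, i:i + m]; i += m
        means = raw[:, i:i + m * d].reshape(b, m, d); i += m * d
        diag_raw = np.clip(raw[:, i:i + m * d].reshape(b, m, d),
                           -_DIAG_CLIP, _DIAG_CLIP); i += m * d
        n_off = d * (d - 1) // 2
        off = raw[:, i:i + m * n_off].reshape(b, m, n_off)
        chol = np.zeros((b, m, d, d))
        idx = np.arange(d)
        chol[:, :, idx, idx] = np.exp(diag_raw)
        chol[:, :, self._tril[0], self._tril[1]] = off
        return logits, means, chol

    def mixture_moments(self, raw: np.ndarray):
        """Weights, means and covariances Σ = (C Cᵀ)⁻¹ from the raw head."""
        logits, means, chol = self.split(raw)
        weights = softmax(logits)
        # Σ = C⁻ᵀ C⁻¹ in Gram form keeps the result PSD even for extreme
        # precisions; a tiny relative diagonal jitter makes it strictly PD
        b, m, d = means.shape
        eye = np.broadcast_to(np.eye(d), chol.shape)
        inv_c = np.linalg.solve(chol, eye)  # triangular inverse
        cov = np.swapaxes(inv_c, -1, -2) @ inv_c
        cov = 0.5 * (cov + np.swapaxes(cov, -1, -2))
        diag_scale = np.einsum("bmii->bm", cov) / d
        cov = cov + (1e-10 * diag_scale)[..., None, None] * np.eye(d)
        return weights, means, cov

    # -- loss and gradient --------------------------------------------------
    def loss_and_grad(self, raw: np.ndarray, targets: np.ndarray):
        """Mean NLL of ``targets`` (B, d) and gradient w.r.t. the raw head."""
        logits, means, chol = self.split(raw)
        targets = np.atleast_2d(np.asarray(targets, dtype=np.float64))
        b, d, m = logits.shape[0], self.d, self.m
        delta = targets[:, None, :] - means  # (B, m, d)
        u = np.einsum("bmij,bmi->bmj", chol, delta)  # Cᵀ δ
        idx = np.arange(d)
        log_det_half = np.log(chol[:, :, idx, idx]).sum(axis=-1)  # Σ log C_kk
        log_g = -0.5 * d * LOG_2PI + log_det_half - 0.5 * (u**2).sum(axis=-1)
        log_pi = logits - _logsumexp(logits)
        t = log_pi + log_g
        log_q = _logsumexp(t)  # (B, 1)
        loss = -float(log_q.mean())

        r = np.exp(t - log_q)  # responsibilities (B, m)
        pi = np.exp(log_pi)
        g_logits = (pi - r) / b
        cu = np.einsum("bmij,bmj->bmi", chol, u)  # C u = Λ δ
        g_means = -(r[..., None] * cu) / b
        # ∂logG/∂C = diag(1/C_kk) − δ uᵀ (lower triangle); the loss flips sign
        g_chol = r[..., None, None] * np.einsum("bmi,bmj->bmij", delta, u) / b
        diag_term = r / b  # via exp reparam: ∂/∂s_k of log C_kk = 1
        g_diag_raw = (-diag_term[..., None]
                      + g_chol[:, :, idx, idx] * chol[:, :, idx, idx])
        g_off = g_chol[:, :, self._tril[0], self._tril[1]]
        grad = np.concatenate([
            g_logits,
            g_means.reshape(b, m * d),
            g_diag_raw.reshape(b, m * d),
            g_off.reshape(b, m * (d * (d - 1) // 2)),
        ], axis=1)
        return loss, grad

    def log_density(self, raw: np.ndarray, targets: np.ndarray) -> np.ndarray:
        """Per-sample log mixture density (no gradient)."""
        logits, means, chol = self.split(raw)
        targets = np.atleast_2d(np.asarray(targets, dtype=np.float64))
        d = self.d
        delta = targets[:, None, :] - means
        u = np.einsum("bmij,bmi->bmj", chol, delta)
        idx = np.arange(d)
        log_det_half = np.log(chol[:, :, idx, idx]).sum(axis=-1)
        log_g = -0.5 * d * LOG_2PI + log_det_half - 0.5 * (u**2).sum(axis=-1)
        log_pi = logits - _logsumexp(logits)
        return _logsumexp(log_pi + log_g)[:, 0]


def _logsumexp(z: np.ndarray) -> np.ndarray:
    zm = z.max(axis=-1, keepdims=True)
    return zm + np.log(np.exp(z - zm).sum(axis=-1, keepdims=True))
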