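"""Dirichlet-multinomial and multinomial log-probabilities and derivatives.

The Dirichlet-multinomial (DM) is parameterised here by a positive vector
``alpha = lambda * p`` where ``p`` is the mean composition and
``lambda = sum(alpha)`` the precision: large ``lambda`` approaches the
multinomial, small ``lambda`` adds overdispersion.  Everything is computed
with log-gamma functions, never factorials, and supports zero counts.

The derivative helpers return the gradient and Hessian of the DM
log-likelihood with respect to the ALR-scale linear predictor ``eta``
(the K-1 log-ratios), which is what the Laplace machinery needs for the
inner Newton optimisation over random intercepts.
"""

from __future__ import annotations

import numpy as np
from scipy.special import gammaln, digamma


def _trigamma(x: np.ndarray) -> np.ndarray:
    """Vectorised trigamma via upward recurrence + asymptotic series.

    Considerably faster than ``scipy.special.polygamma(1, x)`` (which goes
    through the Hurwitz zeta) and accurate to ~1e-12 for positive x; the
    Hessian assembly in the Laplace inner loop is dominated by this call.
    """
    x = np.array(x, dtype=float, copy=True)
    acc = np.zeros_like(x)
    for _ in range(8):  # shift into the asymptotic regime x >= 8
        m = x < 8.0
        if not m.any():
            break
        acc[m] += 1.0 / (x[m] * x[m])
        x[m] += 1.0
    z = 1.0 / (x * x)
    series = 1.0 / 6.0 + z * (-1.0 / 30.0 + z * (1.0 / 42.0 - z / 30.0))
    return acc + 1.0 / x + 0.5 * z + z / x * series

__all__ = ["dm_logpmf", "multinomial_logpmf"]


def _validate_counts_alpha(y: np.ndarray, alpha: np.ndarray) -> None:
    if np.any(y < 0) or not np.allclose(y, np.round(y)):
        raise ValueError("counts must be non-negative integers")
    if np.any(alpha <= 0) or not np.all(np.isfinite(alpha)):
        raise ValueError("alpha must be strictly positive and finite")


def dm_logpmf(y: np.ndarray, alpha: np.ndarray) -> float | np.ndarray:
    """Dirichlet-multinomial log-pmf with total fixed at ``sum(y)``.

    Supports a single pair of K-vectors or matching (N, K) arrays, in which
    case a length-N vector of per-row log-probabilities is returned.
    """
    y = np.asarray(y, dtype=float)
    alpha = np.asarray(alpha, dtype=float)
    _validate_counts_alpha(y, alpha)
    T = y.sum(axis=-1)
    A = alpha.sum(axis=-1)
    return (
        gammaln(T + 1.0)
        - gammaln(y + 1.0).sum(axis=-1)
        + gammaln(A)
        - gammaln(T + A)
        + (gammaln(y + alpha) - gammaln(alpha)).sum(axis=-1)
    )


def multinomial_logpmf(y: np.ndarray, p: np.ndarray) -> float | np.ndarray:
    """Multinomial log-pmf with total fixed at ``sum(y)``.

    Categories with zero probability are allowed only for zero counts.
    """
    y = np.asarray(y, dtype=float)
    p = np.asarray(p, dtype=float)
    if np.any(y < 0) or not np.allclose(y, np.round(y)):
        raise ValueError("counts must be non-negative integers")
    T = y.sum(axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(y > 0, y * np.log(p), 0.0)
    if np.any(~np.isfinite(terms)):
        raise ValueError("zero-probability category with a positive count")
    return gammaln(T + 1.0) - gammaln(y + 1.0).sum(axis=-1) + terms.sum(axis=-1)


# ---------------------------------------------------------------------------
# derivatives with respect to the ALR-scale predictor (internal API)
# ---------------------------------------------------------------------------

def _dm_eta_grad_hess(y, p, lam, need_hess=True):
    """Gradient/Hessian of the DM log-likelihood wrt the first K-1 eta.

    Parameters are row-wise: ``y`` (N, K) counts, ``p`` (N, K) mean
    compositions, ``lam`` (N,) precisions.  Returns ``(ll, grad, hess)``
    where ``grad`` is (N, K-1) and ``hess`` (N, K-1, K-1) (or None).

    Derivation: with alpha = lam * p and softmax p(eta),
      d ll / d eta_m = lam * p_m * (c_m - s),      c_k = psi(y_k+a_k)-psi(a_k),
                                                   s = sum_k p_k c_k,
      H = diag(e) - outer(e, p') - outer(lam*p', p'*(d - dbar)) restricted to
      the first K-1 coordinates, with
      e_m = grad_m + lam^2 * psi1_m * p_m^2,
      psi1_k = psi'(y_k+a_k) - psi'(a_k),  d_k = c_k + lam*p_k*psi1_k.
    """
    K = y.shape[1]
    with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
        alpha = lam[:, None] * p
        ll = (
            gammaln(y.sum(axis=1) + 1.0)
            - gammaln(y + 1.0).sum(axis=1)
            + gammaln(lam)
            - gammaln(y.sum(axis=1) + lam)
            + (gammaln(y + alpha) - gammaln(alpha)).sum(axis=1)
        )
        c = digamma(y + alpha) - digamma(alpha)
        s = (p * c).sum(axis=1)
        grad = lam[:, None] * p[:, : K - 1] * (c[:, : K - 1] - s[:, None])
        if not need_hess:
            return ll, grad, None
        psi1 = _trigamma(y + alpha) - _trigamma(alpha)
        d = c + lam[:, None] * p * psi1
        dbar = (p * d).sum(axis=1)
        e = grad + (lam[:, None] ** 2) * psi1[:, : K - 1] * p[:, : K - 1] ** 2
        pm = p[:, : K - 1]
        hess = (
            np.einsum("nm,mk->nmk", e, np.eye(K - 1))
            - e[:, :, None] * pm[:, None, :]
            - (lam[:, None] * pm)[:, :, None]
            * (pm * (d[:, : K - 1] - dbar[:, None]))[:, None, :]
        )
    return ll, grad, hess


def _multinomial_eta_grad_hess(y, p, need_hess=True):
    """Gradient/Hessian of the multinomial log-likelihood wrt eta (first K-1)."""
    K = y.shape[1]
    T = y.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(y > 0, y * np.log(p), 0.0)
    ll = gammaln(T + 1.0) - gammaln(y + 1.0).sum(axis=1) + terms.sum(axis=1)
    pm = p[:, : K - 1]
    grad = y[:, : K - 1] - T[:, None] * pm
    if not need_hess:
        return ll, grad, None
    hess = -T[:, None, None] * (
        np.einsum("nm,mk->nmk", pm, np.eye(K - 1)) - pm[:, :, None] * pm[:, None, :]
    )
    return ll, grad, hess
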