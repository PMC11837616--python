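"""Additive log-ratio (ALR) transforms for compositional exposure data.

Signature exposures are relative data: only the ratios between signature
activities carry information, so they are modelled on the simplex.  The ALR
transform maps a K-part composition to K-1 log-ratios against a reference
part; its inverse is a generalised softmax.  All softmax-type computations
use max-subtraction so that very large linear predictors stay finite.
"""

from __future__ import annotations

import numpy as np

__all__ = ["alr", "inv_alr", "softmax_coefficients"]


def alr(p: np.ndarray, ref: int = -1) -> np.ndarray:
    """Additive log-ratio transform of a composition.

    Parameters
    ----------
    p : array, shape (K,) or (N, K)
        Strictly positive composition(s); rows need not be normalised
        (the transform only uses ratios).
    ref : int
        Index of the reference part (default: last).  The reference
        coordinate is omitted from the output.

    Returns
    -------
    array, shape (K-1,) or (N, K-1)
        ``log(p_k / p_ref)`` for the non-reference parts, in original order.
    """
    p = np.asarray(p, dtype=float)
    squeeze = p.ndim == 1
    P = np.atleast_2d(p)
    K = P.shape[1]
    ref = ref % K
    if np.any(P <= 0) or not np.all(np.isfinite(P)):
        bad = np.argwhere((P <= 0) | ~np.isfinite(P))
        r, k = bad[0]
        raise ValueError(
            f"alr requires strictly positive finite entries; "
            f"offending category index {k} (row {r}) has value {P[r, k]!r}"
        )
    out = np.log(P / P[:, ref][:, None])
    out = np.delete(out, ref, axis=1)
    return out[0] if squeeze else out


def inv_alr(a: np.ndarray, ref: int = -1) -> np.ndarray:
    """Inverse ALR (generalised softmax): log-ratios back to the simplex.

    The reference part, whose log-ratio is implicitly zero, is re-inserted
    at position ``ref`` and receives ``1 / (1 + sum(exp(a)))``.
    Overflow-safe via max-subtraction.
    """
    a = np.asarray(a, dtype=float)
    if not np.all(np.isfinite(a)):
        raise ValueError("inv_alr requires finite log-ratio entries")
    squeeze = a.ndim == 1
    A = np.atleast_2d(a)
    K = A.shape[1] + 1
    ref = ref % K
    # full log-scale vector with the reference part's implicit zero
    full = np.insert(A, ref, 0.0, axis=1)
    full = full - full.max(axis=1, keepdims=True)
    e = np.exp(full)
    p = e / e.sum(axis=1, keepdims=True)
    return p[0] if squeeze else p


def softmax_coefficients(beta_row: np.ndarray, ref: int = -1) -> np.ndarray:
    """Softmax-transform a row of ALR-scale coefficients to the simplex.

    Appends the implicit zero of the baseline category and applies the
    inverse ALR, so that differences of logs of the output reproduce the
    input coefficient differences (log-ratios are preserved).  Used to read
    group-shift coefficients on the scale of all K signatures, including
    the baseline.
    """
    return inv_alr(np.asarray(beta_row, dtype=float), ref=ref)
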