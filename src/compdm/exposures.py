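"""Signature-exposure extraction by simplex-constrained least squares.

Given known signature definitions S (F categories x K signatures) and an
observation's categorised mutation counts v (length F, total T), exposures
solve

    min_e || v/T - S e ||^2    s.t.  e >= 0,  sum(e) = 1,

a quadratic programme on the simplex.  It is solved as non-negative least
squares with a heavily weighted sum-to-one row (active-set NNLS), followed
by exact renormalisation; integer counts are then formed by
largest-remainder rounding of ``T * e`` so each observation's counts sum
exactly to its total.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.optimize import nnls

from .data import ExposureData, MutationCatalog, SignatureCatalog

__all__ = ["extract_exposures", "downsample_counts", "largest_remainder_round"]

_SUM_WEIGHT = 1e4  # weight of the sum-to-one row in the augmented NNLS


def _simplex_nnls(S: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Least-squares exposures on the simplex for one observation."""
    F, K = S.shape
    A = np.vstack([S, _SUM_WEIGHT * np.ones((1, K))])
    b = np.append(v, _SUM_WEIGHT)
    e, _ = nnls(A, b)
    total = e.sum()
    if total <= 0:
        raise RuntimeError("degenerate NNLS solution (all-zero exposures)")
    return e / total


def largest_remainder_round(e: np.ndarray, total: int) -> np.ndarray:
    """Integer apportionment of ``total`` by largest remainders of total*e."""
    raw = np.asarray(e, dtype=float) * total
    base = np.floor(raw).astype(np.int64)
    short = int(total - base.sum())
    if short > 0:
        order = np.argsort(-(raw - base), kind="stable")
        base[order[:short]] += 1
    return base


def extract_exposures(catalog: MutationCatalog, sigs: SignatureCatalog,
                      active: list[str] | None = None) -> ExposureData:
    """Per-observation QP exposures from a mutation catalog.

    ``active`` restricts the fit to a subset of signatures (the catalog of
    signatures considered active in the cohort); counts are returned so
    that each row sums exactly to the observation's mutation total.
    """
    if active is not None:
        sigs = sigs.subset(list(active))
    if sigs.category_names != catalog.category_names:
        raise ValueError("signature and mutation catalogs disagree in categories")
    S = sigs.S
    if np.linalg.matrix_rank(S) < S.shape[1]:
        warnings.warn("signature definitions are rank-deficient; exposures "
                      "may not be identifiable")
    T = catalog.T
    if np.any(T < 1):
        raise ValueError("every observation needs at least one mutation")
    N, K = catalog.V.shape[1], S.shape[1]
    Y = np.zeros((N, K), dtype=np.int64)
    for j in range(N):
        e = _simplex_nnls(S, catalog.V[:, j] / T[j])
        Y[j] = largest_remainder_round(e, int(T[j]))
    return ExposureData(Y, catalog.patient_id, catalog.group,
                        list(sigs.signature_names))


def extract_proportions(catalog: MutationCatalog, sigs: SignatureCatalog,
                        active: list[str] | None = None) -> np.ndarray:
    """Unrounded simplex exposures (N x K), for diagnostics and tests."""
    if active is not None:
        sigs = sigs.subset(list(active))
    T = catalog.T
    return np.array([
        _simplex_nnls(sigs.S, catalog.V[:, j] / T[j])
        for j in range(catalog.V.shape[1])
    ])


def downsample_counts(data, fraction: float, seed=None):
    """Binomial thinning of every count with retention probability ``fraction``.

    Accepts an ``ExposureData`` or a ``MutationCatalog`` and returns the
    same type with recomputed totals; ``fraction=1`` is the identity.
    Used for robustness checks against lower mutation tolls.
    """
    if not (0.0 < fraction <= 1.0):
        raise ValueError("fraction must lie in (0, 1]")
    if fraction == 1.0:
        return data
    rng = np.random.default_rng(seed)
    if isinstance(data, ExposureData):
        Y = rng.binomial(data.Y, fraction)
        return ExposureData(Y, data.patient_id, data.group,
                            list(data.signature_names))
    if isinstance(data, MutationCatalog):
        V = rng.binomial(data.V, fraction)
        return MutationCatalog(V, list(data.category_names),
                               data.patient_id, data.group)
    raise TypeError("expected ExposureData or MutationCatalog")
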