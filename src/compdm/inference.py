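"""Hypothesis tests and derived summaries for fitted models.

Differential abundance between groups is tested jointly over all K-1
log-ratio shift coefficients with the generalised Wald statistic

    w = beta1_hat' Cov(beta1_hat)^{-1} beta1_hat,    w ~ chi^2_{K-1}

under the null of no shift.  Per-cohort p-values are combined across
cohorts with Benjamini-Hochberg adjustment.  Differential precision
(overdispersion) between groups is tested with a z statistic on the
log-precision shift coefficient.  The shift coefficients can be
softmax-transformed onto the simplex of all K signatures (preserving
log-ratios) and classified as increase / decrease / no-change relative to
the median shift — the minimal-perturbation reading, which assumes most
signatures do not change in absolute abundance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .compositional import softmax_coefficients
from .model import DirichletMultinomialMixedModel

__all__ = [
    "WaldResult",
    "wald_test",
    "adjust_pvalues",
    "precision_shift_test",
    "softmax_beta",
    "minimal_perturbation_classify",
    "results_table",
]


@dataclass(frozen=True)
class WaldResult:
    """Generalised Wald test of a coefficient row against zero."""

    w: float
    df: int
    p_value: float


def wald_test(fit: DirichletMultinomialMixedModel, row: int = 1) -> WaldResult:
    """Joint chi-square test that one row of the fixed effects is zero.

    The default row (1) is the group-shift vector, i.e. the test of overall
    differential abundance.
    """
    fit._check_fitted()
    if fit.vcov_ is None:
        raise ValueError("Wald test needs a converged fit with a covariance; "
                         "consider reducing the signature set")
    b = np.asarray(fit.coef_[row], dtype=float)
    V = fit.beta_covariance(row)
    try:
        w = float(b @ np.linalg.solve(V, b))
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "singular coefficient covariance block; the signature set may "
            "contain near-redundant or nearly-always-zero signatures"
        ) from exc
    df = b.size
    return WaldResult(w=w, df=df, p_value=float(stats.chi2.sf(w, df)))


def adjust_pvalues(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, clipped at 1)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def precision_shift_test(fit: DirichletMultinomialMixedModel, coef: int = 1):
    """Two-sided z test of a log-precision shift coefficient.

    A positive estimate means the non-reference group is *less* dispersed
    (higher precision).  Returns ``(z, p_value)``.
    """
    fit._check_fitted()
    theta = fit.precision_coef_
    if theta.size < 2:
        raise ValueError(
            f"variant {fit.variant!r} has no group precision contrast"
        )
    if fit.vcov_ is None:
        raise ValueError("precision test needs a converged fit with a covariance")
    sl = fit.param_slices_["theta"]
    idx = sl.start + coef
    se = float(np.sqrt(fit.vcov_[idx, idx]))
    z = float(theta[coef] / se)
    return z, float(2.0 * stats.norm.sf(abs(z)))


def softmax_beta(beta_row) -> np.ndarray:
    """Shift coefficients mapped to the K-simplex (baseline appended as 0)."""
    return softmax_coefficients(beta_row)


def minimal_perturbation_classify(beta_row, se_row, z: float = 1.96,
                                  names=None) -> pd.DataFrame:
    """Classify signatures as increase / decrease / no-change.

    The baseline category is augmented with estimate 0 (its own log-ratio)
    and zero standard error; each signature whose ``estimate ± z*se``
    interval lies entirely above (below) the median of the augmented
    estimates is labelled increase (decrease), otherwise no-change.  Valid
    when most signatures do not change in absolute abundance.
    """
    b = np.append(np.asarray(beta_row, dtype=float), 0.0)
    se = np.append(np.asarray(se_row, dtype=float), 0.0)
    if np.any(se < 0):
        raise ValueError("standard errors must be non-negative")
    m = np.median(b)
    lower, upper = b - z * se, b + z * se
    label = np.where(lower > m, "increase", np.where(upper < m, "decrease", "no-change"))
    if names is None:
        names = [f"S{k + 1}" for k in range(b.size)]
    return pd.DataFrame({"signature": list(names), "estimate": b,
                         "se": se, "label": label})


def results_table(fit: DirichletMultinomialMixedModel) -> pd.DataFrame:
    """Tidy per-signature summary of a fitted two-group model."""
    fit._check_fitted()
    K = fit.coef_.shape[1] + 1
    names = fit.signature_names_
    b0 = np.append(fit.coef_[0], np.nan)
    b1 = np.append(fit.coef_[1], np.nan) if fit.coef_.shape[0] > 1 else np.full(K, np.nan)
    se0 = se1 = np.full(K, np.nan)
    if fit.vcov_ is not None:
        se0 = np.append(fit.beta_se(0), np.nan)
        if fit.coef_.shape[0] > 1:
            se1 = np.append(fit.beta_se(1), np.nan)
    sm = softmax_beta(fit.coef_[1]) if fit.coef_.shape[0] > 1 else np.full(K, np.nan)
    df = pd.DataFrame({
        "signature": names,
        "beta0": b0, "se0": se0,
        "beta1": b1, "se1": se1,
        "softmax_beta1": sm,
    })
    if fit.vcov_ is not None and fit.coef_.shape[0] > 1:
        lab = minimal_perturbation_classify(fit.coef_[1], fit.beta_se(1),
                                            names=names)
        df["label"] = lab["label"].to_numpy()
    return df
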