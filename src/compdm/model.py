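"""Mixed-effects Dirichlet-multinomial regression, fitted by Laplace-
approximated marginal maximum likelihood.

Model
-----
For observation j with counts ``y_j`` (K signatures, total ``T_j``):

    u_i ~ MVN(0, Sigma)                         patient random intercepts
    eta_j = x_j' beta + z_j' U                  ALR-scale linear predictor
    p_j = inv_alr(eta_j)                        mean composition
    log lambda_j = d_j' theta                   precision (log link)
    y_j ~ DM(lambda_j * p_j, T_j)

The random intercepts are integrated out with the Laplace approximation:
an inner Newton optimisation finds the per-patient posterior mode (the
problem separates over patients because Z is a patient indicator), and the
marginal negative log-likelihood adds half the log-determinant of each
per-patient Hessian.  The outer optimisation over all fixed parameters is
quasi-Newton with finite-difference gradients; standard errors come from
the numerically differentiated Hessian of the marginal NLL at the optimum.

Variants differ in the random-effect structure (none, scalar, diagonal or
full covariance via an unconstrained Cholesky factor) and in the precision
structure (single, per precision-design column, or per patient); ``fullREM``
replaces the DM likelihood with a plain multinomial.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from sklearn.base import BaseEstimator

from .compositional import alr
from .data import DesignSet, ExposureData, ModelSpec, build_design
from .dm import _dm_eta_grad_hess, _multinomial_eta_grad_hess

__all__ = [
    "DirichletMultinomialMixedModel",
    "fit_model",
    "joint_nll",
    "laplace_marginal_nll",
    "linear_predictor",
    "precision_predictor",
    "predict_random_effects",
    "InnerConvergenceError",
]

_LOG2PI = np.log(2.0 * np.pi)


class InnerConvergenceError(RuntimeError):
    """Inner (random-effect mode) Newton optimisation failed to converge."""

    def __init__(self, patient: int, grad_norm: float):
        self.patient = patient
        self.grad_norm = grad_norm
        super().__init__(
            f"inner optimisation did not converge for patient index {patient} "
            f"(gradient norm {grad_norm:.3e})"
        )


def _softmax_ref_last(eta: np.ndarray) -> np.ndarray:
    """inv_alr for (N, K-1) predictors with the reference category last."""
    full = np.concatenate([eta, np.zeros((eta.shape[0], 1))], axis=1)
    full -= full.max(axis=1, keepdims=True)
    e = np.exp(full)
    return e / e.sum(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# parameter packing
# ---------------------------------------------------------------------------

@dataclass
class _Layout:
    """Shapes and slices of the packed fixed-parameter vector."""

    P: int
    K: int
    Q: int
    n_patients: int
    spec: ModelSpec

    @property
    def re_dim(self) -> int:
        return {"none": 0, "scalar": 1, "diagonal": self.K - 1, "full": self.K - 1}[
            self.spec.re_structure
        ]

    @property
    def n_beta(self) -> int:
        return self.P * (self.K - 1)

    @property
    def n_theta(self) -> int:
        return {
            "none": 0,
            "single": 1,
            "by_d": self.Q,
            "per_patient": self.n_patients,
        }[self.spec.precision_structure]

    @property
    def n_re(self) -> int:
        d = self.K - 1
        return {"none": 0, "scalar": 1, "diagonal": d, "full": d * (d + 1) // 2}[
            self.spec.re_structure
        ]

    @property
    def size(self) -> int:
        return self.n_beta + self.n_theta + self.n_re

    @property
    def slices(self) -> dict[str, slice]:
        a, b = self.n_beta, self.n_beta + self.n_theta
        return {
            "beta": slice(0, a),
            "theta": slice(a, b),
            "re": slice(b, b + self.n_re),
        }

    def beta_row(self, r: int) -> slice:
        return slice(r * (self.K - 1), (r + 1) * (self.K - 1))

    def unpack(self, x: np.ndarray):
        s = self.slices
        beta = x[s["beta"]].reshape(self.P, self.K - 1)
        return beta, x[s["theta"]], x[s["re"]]

    def sigma(self, re_params: np.ndarray):
        """(Sigma, Sigma_inv, logdet Sigma) for the random-effect prior."""
        struct = self.spec.re_structure
        if struct == "none":
            return None, None, None
        if struct == "scalar":
            s2 = np.exp(2.0 * re_params[0])
            return np.array([[s2]]), np.array([[1.0 / s2]]), np.log(s2)
        d = self.K - 1
        if struct == "diagonal":
            s2 = np.exp(2.0 * re_params)
            return np.diag(s2), np.diag(1.0 / s2), float(np.sum(np.log(s2)))
        # full: lower-triangular Cholesky, log-diagonal first then off-diagonals
        L = np.zeros((d, d))
        L[np.diag_indices(d)] = np.exp(re_params[:d])
        if d > 1:
            L[np.tril_indices(d, -1)] = re_params[d:]
        Sigma = L @ L.T
        Linv = np.linalg.inv(L)  # small d; structural PD
        return Sigma, Linv.T @ Linv, 2.0 * float(np.sum(re_params[:d]))


# ---------------------------------------------------------------------------
# Laplace engine
# ---------------------------------------------------------------------------

class _LaplaceEngine:
    """Vectorised inner Newton + marginal NLL for one dataset/design/spec.

    Observations must be ordered so each patient's rows are contiguous
    (the estimator normalises ordering before constructing the engine).
    """

    def __init__(self, Y, design: DesignSet, spec: ModelSpec,
                 inner_tol=1e-10, inner_max_iter=50):
        self.Y = np.asarray(Y, dtype=float)
        self.X = design.X
        self.D = design.D
        self.spec = spec
        self.inner_tol = inner_tol
        self.inner_max_iter = inner_max_iter
        pat = design.patient_index
        if np.any(np.diff(pat) < 0):
            raise ValueError("observations must be grouped contiguously by patient")
        self.pat = pat
        self.n_patients = design.n_patients
        self.starts = np.searchsorted(pat, np.arange(self.n_patients))
        self.layout = _Layout(
            P=self.X.shape[1], K=self.Y.shape[1], Q=self.D.shape[1],
            n_patients=self.n_patients, spec=spec,
        )
        self.U = np.zeros((self.n_patients, max(self.layout.re_dim, 1)))
        # inner gradient tolerance scales with each patient's count total:
        # the log-likelihood (and its float64 rounding noise) is O(T)
        patient_T = np.add.reduceat(self.Y.sum(axis=1), self.starts)
        scale = np.maximum(1.0, np.sqrt(patient_T))
        # target tolerance: essentially machine-tight so the marginal NLL is
        # a smooth function of the fixed parameters (the log-det term is
        # linear in the mode error); failure threshold is far looser
        self.inner_tol_vec = inner_tol * scale
        self.inner_fail_vec = 1e-5 * scale
        self.nll_path: list[float] = []

    # -- helpers ------------------------------------------------------------

    def lambdas(self, theta: np.ndarray) -> np.ndarray | None:
        ps = self.spec.precision_structure
        if ps == "none":
            return None
        if ps == "single":
            return np.full(self.Y.shape[0], np.exp(theta[0]))
        if ps == "per_patient":
            return np.exp(theta[self.pat])
        return np.exp(self.D @ theta)

    def _eta(self, Xbeta: np.ndarray, U: np.ndarray) -> np.ndarray:
        if self.spec.re_structure == "none":
            return Xbeta
        if self.spec.re_structure == "scalar":
            return Xbeta + U[self.pat, 0][:, None]
        return Xbeta + U[self.pat]

    def _loglik_terms(self, eta, lam, need_hess):
        p = _softmax_ref_last(eta)
        if self.spec.likelihood == "multinomial":
            return _multinomial_eta_grad_hess(self.Y, p, need_hess)
        return _dm_eta_grad_hess(self.Y, p, lam, need_hess)

    def _per_patient(self, arr, axis=0):
        return np.add.reduceat(arr, self.starts, axis=axis)

    def _u_grad_hess(self, grad_eta, hess_eta):
        """Map eta-scale derivatives to per-patient u-space (log-likelihood)."""
        if self.spec.re_structure == "scalar":
            g = self._per_patient(grad_eta.sum(axis=1))[:, None]
            H = self._per_patient(hess_eta.sum(axis=(1, 2)))[:, None, None]
            return g, H
        g = self._per_patient(grad_eta)
        H = self._per_patient(hess_eta)
        return g, H

    def _objective_per_patient(self, ll, U, Sigma_inv):
        """-loglik + RE prior quadratic, per patient (constants excluded)."""
        f = -self._per_patient(ll)
        if self.spec.re_structure == "scalar":
            f = f + 0.5 * Sigma_inv[0, 0] * U[:, 0] ** 2
        else:
            f = f + 0.5 * np.einsum("id,de,ie->i", U, Sigma_inv, U)
        return f

    # -- inner Newton -------------------------------------------------------

    def inner_newton(self, Xbeta, lam, Sigma_inv, U0=None, raise_on_fail=True):
        """Per-patient posterior modes of the random intercepts.

        Returns (U_hat, f_per_patient, H_per_patient) where ``f`` is the
        joint NLL contribution (without prior normalising constants) and
        ``H`` the per-patient Hessian of the joint NLL at the mode.
        """
        d = self.layout.re_dim
        U = np.zeros((self.n_patients, d)) if U0 is None else U0.copy()
        ll, grad_eta, hess_eta = self._loglik_terms(self._eta(Xbeta, U), lam, True)
        f = self._objective_per_patient(ll, U, Sigma_inv)
        stalled = np.zeros(self.n_patients, dtype=bool)
        for _ in range(self.inner_max_iter):
            g_ll, H_ll = self._u_grad_hess(grad_eta, hess_eta)
            grad = -g_ll + U @ Sigma_inv
            H = -H_ll + Sigma_inv
            gnorm = np.linalg.norm(grad, axis=1)
            if np.all((gnorm < self.inner_tol_vec) | stalled):
                break
            # modified Newton direction: clamp eigenvalues so the step is a
            # guaranteed descent direction even for indefinite or
            # near-singular per-patient Hessians
            w, Q = np.linalg.eigh(H)
            floor = np.maximum(1e-8, 1e-8 * np.abs(w).max(axis=1, keepdims=True))
            w_safe = np.maximum(np.abs(w), floor)
            step = np.einsum("imk,ik,ilk,il->im", Q, 1.0 / w_safe, Q, grad)
            # per-patient step-halving line search; never accept an uphill move
            t = np.ones(self.n_patients)
            active = (gnorm >= self.inner_tol_vec) & ~stalled
            noise = 1e-11 * np.maximum(1.0, np.abs(f))
            for _halve in range(12):
                U_try = U - t[:, None] * step * active[:, None]
                ll2, g2, h2 = self._loglik_terms(self._eta(Xbeta, U_try), lam, True)
                f_try = self._objective_per_patient(ll2, U_try, Sigma_inv)
                worse = active & (~np.isfinite(f_try) | (f_try > f + noise))
                if not worse.any():
                    break
                t[worse] *= 0.5
            if worse.any():
                # patients whose line search failed stay put and are frozen:
                # repeating a futile search every iteration is pure waste
                stalled |= worse
                U_try[worse] = U[worse]
                ll2, g2, h2 = self._loglik_terms(self._eta(Xbeta, U_try), lam, True)
            U, ll, grad_eta, hess_eta = U_try, ll2, g2, h2
            f = self._objective_per_patient(ll, U, Sigma_inv)
        g_ll, H_ll = self._u_grad_hess(grad_eta, hess_eta)
        grad = -g_ll + U @ Sigma_inv
        H = -H_ll + Sigma_inv
        gnorm = np.linalg.norm(grad, axis=1)
        rel = gnorm / self.inner_fail_vec
        if rel.max() >= 1.0 and raise_on_fail:
            raise InnerConvergenceError(int(rel.argmax()), float(gnorm[rel.argmax()]))
        f = self._objective_per_patient(ll, U, Sigma_inv)
        return U, f, H

    # -- marginal NLL -------------------------------------------------------

    def marginal_nll(self, x, warm=True, update=False, raise_on_fail=True):
        """Laplace-approximated marginal NLL at packed fixed parameters.

        For variants without random effects this is the exact NLL.  The
        inner Newton warm-starts from the stored anchor ``self.U``; the
        anchor is only advanced when ``update=True`` (the outer optimiser
        does so at accepted iterates), which keeps the objective a
        deterministic function of ``x`` during finite differencing.
        """
        beta, theta, re_params = self.layout.unpack(np.asarray(x, dtype=float))
        lam = self.lambdas(theta)
        Xbeta = self.X @ beta
        if self.spec.re_structure == "none":
            ll, _, _ = self._loglik_terms(Xbeta, lam, False)
            return float(-ll.sum())
        _, Sigma_inv, logdetS = self.layout.sigma(re_params)
        U0 = self.U if warm else None
        U, f, H = self.inner_newton(Xbeta, lam, Sigma_inv, U0=U0,
                                    raise_on_fail=raise_on_fail)
        if update:
            self.U = U
        d = self.layout.re_dim
        sign, logdetH = np.linalg.slogdet(H)
        if np.any(sign <= 0):
            raise np.linalg.LinAlgError("non-PD Hessian at random-effect mode")
        joint = f.sum() + self.n_patients * 0.5 * (logdetS + d * _LOG2PI)
        return float(joint + 0.5 * logdetH.sum() - self.n_patients * d / 2.0 * _LOG2PI)

    def safe_nll(self, x, update=False):
        """Objective for the outer optimiser: large finite value on failure."""
        try:
            with np.errstate(over="ignore", invalid="ignore"):
                v = self.marginal_nll(x, update=update)
        except (np.linalg.LinAlgError, InnerConvergenceError, FloatingPointError):
            return 1e10
        return v if np.isfinite(v) else 1e10

    def advance_anchor(self, x):
        """Move the warm-start anchor to the mode at ``x`` (best effort).

        Also records the objective at accepted iterates (``nll_path``),
        which lets callers verify the line-search descent contract.
        """
        try:
            v = self.marginal_nll(x, update=True, raise_on_fail=False)
            self.nll_path.append(float(v))
        except (np.linalg.LinAlgError, FloatingPointError):
            pass

    # -- initial values -----------------------------------------------------

    def initial_params(self) -> np.ndarray:
        lay = self.layout
        K = lay.K
        x0 = np.zeros(lay.size)
        # beta0 from the pooled composition of reference-group rows
        if lay.P >= 2 and set(np.unique(self.X[:, 1])) <= {0.0, 1.0}:
            rows = self.X[:, 1] == 0
        else:
            rows = np.ones(self.Y.shape[0], dtype=bool)
        pooled = self.Y[rows].sum(axis=0).astype(float)
        pooled[pooled == 0] = 0.5  # pseudocount keeps the ALR finite
        x0[lay.beta_row(0)] = alr(pooled / pooled.sum(), ref=-1)
        s = lay.slices
        if lay.n_theta:
            th = np.zeros(lay.n_theta)
            if self.spec.precision_structure == "per_patient":
                th[:] = np.log(50.0)
            else:
                th[0] = np.log(50.0)
            x0[s["theta"]] = th
        if lay.n_re:
            re0 = np.zeros(lay.n_re)
            ndiag = {"scalar": 1, "diagonal": K - 1, "full": K - 1}[
                self.spec.re_structure
            ]
            re0[:ndiag] = np.log(0.5)
            x0[s["re"]] = re0
        return x0


def _central_gradient(fun, x, step=1e-6):
    """Central-difference gradient (accurate when ``fun`` is smooth)."""
    x = np.asarray(x, dtype=float)
    g = np.empty_like(x)
    h = step * np.maximum(1.0, np.abs(x))
    for i in range(x.size):
        e = np.zeros_like(x)
        e[i] = h[i]
        g[i] = (fun(x + e) - fun(x - e)) / (2.0 * h[i])
    return g


def _numerical_hessian(fun, x, step=1e-4):
    """Central-difference Hessian of a scalar function."""
    x = np.asarray(x, dtype=float)
    p = x.size
    h = step * np.maximum(1.0, np.abs(x))
    H = np.empty((p, p))
    f0 = fun(x)
    for i in range(p):
        ei = np.zeros(p)
        ei[i] = h[i]
        fpp = fun(x + ei)
        fmm = fun(x - ei)
        H[i, i] = (fpp - 2.0 * f0 + fmm) / h[i] ** 2
        for j in range(i + 1, p):
            ej = np.zeros(p)
            ej[j] = h[j]
            fa = fun(x + ei + ej)
            fb = fun(x + ei - ej)
            fc = fun(x - ei + ej)
            fd = fun(x - ei - ej)
            H[i, j] = H[j, i] = (fa - fb - fc + fd) / (4.0 * h[i] * h[j])
    return H


# ---------------------------------------------------------------------------
# estimator
# ---------------------------------------------------------------------------

class DirichletMultinomialMixedModel(BaseEstimator):
    """Dirichlet-multinomial mixed-effects compositional regression.

    Parameters
    ----------
    variant : str
        One of ``diagREDM`` (per-log-ratio random intercepts, group
        precision; the recommended default), ``fullREDM`` (correlated
        random intercepts), ``singleREDM`` (one scalar intercept per
        patient), ``fullREM`` (multinomial, correlated intercepts),
        ``FEDMsinglelambda`` (fixed effects only, one precision) and
        ``diagREDMpatientlambda`` (per-patient precision).
    ref_category : int or None
        Column of Y used as the ALR baseline (default: last).  Internally
        categories are rotated so the reference is last and results are
        reported in that rotated order (``signature_names_``).
    inner_tol, inner_max_iter : float, int
        Newton tolerance (gradient norm) and iteration cap for the
        per-patient random-effect modes.
    outer_tol, outer_max_iter : float, int
        Quasi-Newton (L-BFGS) tolerance and iteration cap for the fixed
        parameters.
    compute_vcov : bool
        Whether to numerically differentiate the marginal NLL at the
        optimum for standard errors (needed for Wald tests).

    Attributes
    ----------
    coef_ : (P, K-1) array
        Fixed effects on the ALR scale; row 0 is the baseline composition,
        row 1 the group shift (differential abundance) in the default
        design.
    precision_coef_ : array
        Log-precision coefficients (empty for ``fullREM``).
    covariance_ : (d, d) array or None
        Estimated random-intercept covariance ``Sigma``.
    random_effects_ : (N_s, d) array or None
        Posterior-mode random intercepts.
    vcov_ : array or None
        Covariance of all packed fixed parameters (inverse numerical
        Hessian of the marginal NLL).
    nll_ : float
        Minimised marginal negative log-likelihood.
    converged_ : bool
    """

    def __init__(self, variant="diagREDM", ref_category=None,
                 inner_tol=1e-10, inner_max_iter=50,
                 outer_tol=1e-6, outer_max_iter=200, outer_ftol=1e-11,
                 compute_vcov=True, hess_step=1e-3, fd_step=1e-5,
                 polish=True):
        self.variant = variant
        self.ref_category = ref_category
        self.inner_tol = inner_tol
        self.inner_max_iter = inner_max_iter
        self.outer_tol = outer_tol
        self.outer_max_iter = outer_max_iter
        self.outer_ftol = outer_ftol
        self.compute_vcov = compute_vcov
        self.hess_step = hess_step
        self.fd_step = fd_step
        self.polish = polish

    # -- fitting ------------------------------------------------------------

    def fit(self, X, Y, groups=None, D=None, signature_names=None):
        """Fit the model.

        Parameters
        ----------
        X : (N, P) array
            Fixed-effect design (first column conventionally an intercept;
            second a 0/1 group indicator in the two-group design).
        Y : (N, K) array
            Non-negative integer exposure counts.
        groups : length-N array-like, optional
            Patient labels for the random intercepts.  Required for
            random-effect variants.
        D : (N, Q) array, optional
            Precision design; defaults to X for group-precision variants.
        """
        spec = ModelSpec(self.variant, self.ref_category)
        X = np.asarray(X, dtype=float)
        Y = np.asarray(Y)
        if X.ndim != 2 or Y.ndim != 2 or X.shape[0] != Y.shape[0]:
            raise ValueError(
                f"conformability: X is {X.shape}, Y is {Y.shape}; "
                "expected matching row counts and 2-D arrays"
            )
        if np.any(Y < 0) or not np.allclose(Y, np.round(Y)):
            raise ValueError("Y must contain non-negative integer counts")
        K = Y.shape[1]
        if K < 2:
            raise ValueError("need at least two categories")
        names = list(signature_names) if signature_names is not None \
            else [f"S{k + 1}" for k in range(K)]

        # rotate the reference category to the last column
        ref = (K - 1) if self.ref_category is None else self.ref_category % K
        order = [k for k in range(K) if k != ref] + [ref]
        Y = Y[:, order]
        self.signature_names_ = [names[k] for k in order]
        self.category_order_ = np.array(order)

        need_re = spec.re_structure != "none"
        if groups is None:
            if need_re:
                raise ValueError(f"variant {self.variant} requires patient groups")
            groups = np.arange(X.shape[0])
        groups = np.asarray(groups)
        # contiguous-by-patient row order (stable within patient)
        uniq = pd.unique(groups)
        pat_rank = {p: i for i, p in enumerate(uniq)}
        row_order = np.argsort([pat_rank[g] for g in groups], kind="stable")
        self._row_order = row_order
        Xs, Ys, gs = X[row_order], Y[row_order], groups[row_order]
        Z = np.zeros((len(gs), len(uniq)))
        for j, g in enumerate(gs):
            Z[j, pat_rank[g]] = 1.0
        self.patient_labels_ = np.asarray(uniq)

        if spec.precision_structure == "single":
            Dmat = np.ones((Xs.shape[0], 1))
        elif D is not None:
            Dmat = np.asarray(D, dtype=float)[row_order]
        else:
            Dmat = Xs.copy()
        design = DesignSet(X=Xs, Z=Z, D=Dmat)
        if need_re and design.n_patients < 2:
            raise ValueError("random-effect variants need at least 2 patients")

        engine = _LaplaceEngine(Ys, design, spec,
                                inner_tol=self.inner_tol,
                                inner_max_iter=self.inner_max_iter)
        self._engine = engine
        x0 = engine.initial_params()

        def obj(x):
            v = engine.safe_nll(x)
            return v

        res = minimize(
            obj, x0, method="L-BFGS-B",
            callback=engine.advance_anchor,
            options={
                "maxiter": self.outer_max_iter,
                "gtol": self.outer_tol,
                "ftol": self.outer_ftol,
                "eps": self.fd_step,
                "maxcor": 25,
            },
        )
        # a central-difference rescue pass is worthwhile only when the
        # forward-difference run aborted on a failed line search (status 2)
        # or never produced a finite value; an exhausted iteration budget
        # (status 1) means the problem, not the gradient accuracy, is the
        # obstacle, and repeating the whole run would double the cost
        if res.fun >= 1e9 or (not res.success and res.status == 2):
            res2 = minimize(
                engine.safe_nll, res.x if res.fun < 1e9 else x0,
                method="L-BFGS-B", jac="3-point",
                callback=engine.advance_anchor,
                options={"maxiter": self.outer_max_iter,
                         "gtol": self.outer_tol, "ftol": self.outer_ftol,
                         "maxcor": 25},
            )
            if res2.fun <= res.fun:
                res = res2
        xhat = res.x
        self.params_ = xhat
        self.nll_path_ = list(engine.nll_path)
        lay = engine.layout
        beta, theta, re_params = lay.unpack(xhat)
        self.coef_ = beta
        self.precision_coef_ = theta
        self.re_params_ = re_params
        Sigma, _, _ = lay.sigma(re_params)
        self.covariance_ = Sigma
        self.nll_ = float(res.fun)
        self.n_iter_ = int(res.nit)
        self.grad_norm_ = float(np.max(np.abs(res.jac))) if res.jac is not None else np.nan
        self.converged_ = bool(res.success or self.grad_norm_ <= 1e-3)
        self.param_slices_ = lay.slices
        self.layout_ = lay

        # posterior-mode random intercepts at the optimum
        if spec.re_structure != "none":
            try:
                engine.marginal_nll(xhat, warm=True, update=True)
                self.random_effects_ = engine.U.copy()
            except (np.linalg.LinAlgError, InnerConvergenceError):
                self.random_effects_ = None
                self.converged_ = False
        else:
            self.random_effects_ = None

        self.vcov_ = None
        if self.compute_vcov and self.nll_ < 1e9:
            H = _numerical_hessian(engine.safe_nll, xhat, step=self.hess_step)
            Hs = (H + H.T) / 2.0
            if self.polish:
                xp, moved = self._newton_polish(engine, xhat, Hs)
                if moved:
                    xhat = xp
                    self.params_ = xhat
                    beta, theta, re_params = lay.unpack(xhat)
                    self.coef_, self.precision_coef_ = beta, theta
                    self.re_params_ = re_params
                    self.covariance_ = lay.sigma(re_params)[0]
                    self.nll_ = float(engine.safe_nll(xhat))
                    engine.advance_anchor(xhat)
                    if spec.re_structure != "none":
                        self.random_effects_ = engine.U.copy()
                    H = _numerical_hessian(engine.safe_nll, xhat,
                                           step=self.hess_step)
                    Hs = (H + H.T) / 2.0
            # random-effect variances estimated at the zero boundary leave
            # the marginal NLL flat in their log-SD coordinate; prune those
            # directions and report SEs for the remaining parameters
            diagH = np.abs(np.diag(Hs))
            re_sl = lay.slices["re"]
            keep = np.ones(lay.size, dtype=bool)
            for i in range(re_sl.start, re_sl.stop):
                if diagH[i] < 1e-5 * diagH.max():
                    keep[i] = False
            try:
                Hk = Hs[np.ix_(keep, keep)]
                eigvals = np.linalg.eigvalsh(Hk)
                if eigvals.min() <= 0:
                    raise np.linalg.LinAlgError("marginal-NLL Hessian not PD")
                V = np.zeros_like(Hs)
                V[np.ix_(keep, keep)] = np.linalg.inv(Hk)
                self.vcov_ = V
            except np.linalg.LinAlgError:
                self.vcov_ = None
                self.converged_ = False
        elif self.nll_ >= 1e9:
            self.converged_ = False
        return self

    def _newton_polish(self, engine, x, H):
        """A few Newton steps with accurate central-difference gradients.

        Quasi-Newton termination leaves the iterate within finite-difference
        noise of the optimum; polishing pins it down so refits (e.g. under a
        permuted category order) agree to tight tolerances.  Returns the
        polished point and whether it moved materially.
        """
        try:
            np.linalg.cholesky(H)
        except np.linalg.LinAlgError:
            return x, False
        x_cur = np.asarray(x, dtype=float).copy()
        f_cur = engine.safe_nll(x_cur)
        moved = False
        for _ in range(4):
            g = _central_gradient(engine.safe_nll, x_cur, step=1e-6)
            delta = np.linalg.solve(H, g)
            if not np.all(np.isfinite(delta)):
                break
            accepted = False
            for t in (1.0, 0.5, 0.25, 0.125):
                x_new = x_cur - t * delta
                f_new = engine.safe_nll(x_new)
                if f_new <= f_cur + 1e-9 * max(1.0, abs(f_cur)):
                    x_cur, f_cur, accepted = x_new, min(f_new, f_cur), True
                    break
            if not accepted:
                break
            moved = True
            if np.linalg.norm(delta) < 1e-9:
                break
        return x_cur, moved

    # -- accessors ----------------------------------------------------------

    def _check_fitted(self):
        if not hasattr(self, "coef_"):
            raise RuntimeError("model is not fitted")

    @property
    def lambda_(self) -> np.ndarray:
        """Fitted precision levels implied by the precision coefficients."""
        self._check_fitted()
        lam = self._engine.lambdas(self.precision_coef_)
        if lam is None:
            raise AttributeError("fullREM has no precision parameter")
        return lam

    def beta_covariance(self, row: int = 1) -> np.ndarray:
        """(K-1, K-1) covariance sub-block of one row of ``coef_``."""
        self._check_fitted()
        if self.vcov_ is None:
            raise ValueError("covariance unavailable (fit did not converge)")
        idx = np.arange(*self.layout_.beta_row(row).indices(self.layout_.n_beta))
        return self.vcov_[np.ix_(idx, idx)]

    def beta_se(self, row: int = 1) -> np.ndarray:
        return np.sqrt(np.diag(self.beta_covariance(row)))

    def predict_proba(self, X) -> np.ndarray:
        """Expected compositions from the fixed effects, original category order."""
        self._check_fitted()
        eta = np.asarray(X, dtype=float) @ self.coef_
        p = _softmax_ref_last(eta)
        inv = np.argsort(self.category_order_)
        return p[:, inv]

    def correlation_(self) -> np.ndarray:
        """Correlation matrix of the estimated random-intercept covariance."""
        self._check_fitted()
        if self.covariance_ is None:
            raise ValueError("variant has no random-effect covariance")
        sd = np.sqrt(np.diag(self.covariance_))
        return self.covariance_ / np.outer(sd, sd)


# ---------------------------------------------------------------------------
# module-level operations (thin wrappers)
# ---------------------------------------------------------------------------

def fit_model(data: ExposureData, variant="diagREDM", ref_category=None,
              ref_group=None, **options) -> DirichletMultinomialMixedModel:
    """Fit a variant to an ``ExposureData`` with the default matched design."""
    data = data.sort_normalised(ref_group=ref_group).validate()
    design = build_design(data, ref_group=ref_group)
    est = DirichletMultinomialMixedModel(variant=variant,
                                         ref_category=ref_category, **options)
    return est.fit(design.X, data.Y, groups=data.patient_id, D=design.D,
                   signature_names=data.signature_names)


def _engine_for(data: ExposureData, design: DesignSet, spec: ModelSpec,
                **kw) -> _LaplaceEngine:
    return _LaplaceEngine(data.Y, design, spec, **kw)


def joint_nll(beta, theta, Sigma, U, data: ExposureData, design: DesignSet,
              spec: ModelSpec) -> float:
    """Joint NLL of counts and random intercepts at given parameter values.

    ``-sum_j log f(y_j | u) - sum_i log MVN(u_i; 0, Sigma)``; the MVN term
    is absent for variants without random effects, and the DM likelihood is
    replaced by the multinomial for ``fullREM``.
    """
    eng = _engine_for(data, design, spec)
    beta = np.asarray(beta, dtype=float)
    lam = eng.lambdas(np.asarray(theta, dtype=float)) if spec.precision_structure != "none" else None
    if spec.re_structure == "none":
        ll, _, _ = eng._loglik_terms(design.X @ beta, lam, False)
        return float(-ll.sum())
    U = np.asarray(U, dtype=float)
    Sigma = np.atleast_2d(np.asarray(Sigma, dtype=float))
    sign, logdetS = np.linalg.slogdet(Sigma)
    if sign <= 0:
        raise ValueError("Sigma must be positive definite")
    Sigma_inv = np.linalg.inv(Sigma)
    ll, _, _ = eng._loglik_terms(eng._eta(design.X @ beta, U), lam, False)
    d = U.shape[1]
    quad = 0.5 * np.einsum("id,de,ie->", U, Sigma_inv, U)
    prior = quad + U.shape[0] * 0.5 * (logdetS + d * _LOG2PI)
    return float(-ll.sum() + prior)


def laplace_marginal_nll(x_packed, data: ExposureData, design: DesignSet,
                         spec: ModelSpec, **kw):
    """Laplace marginal NLL at packed fixed parameters; returns (value, U_hat)."""
    eng = _engine_for(data, design, spec, **kw)
    value = eng.marginal_nll(np.asarray(x_packed, dtype=float), warm=True, update=True)
    return value, eng.U.copy()


def linear_predictor(X, beta, Z=None, U=None) -> np.ndarray:
    """ALR-scale mean predictor ``X @ beta + Z @ U`` (N x (K-1)).

    Rows are mapped to compositions with :func:`compdm.inv_alr`.  ``Z``/``U``
    default to no random-effect contribution.
    """
    X = np.asarray(X, dtype=float)
    beta = np.asarray(beta, dtype=float)
    if X.ndim != 2 or beta.ndim != 2 or X.shape[1] != beta.shape[0]:
        raise ValueError(
            f"shape mismatch: X is {X.shape}, beta is {beta.shape}; "
            f"expected X (N, P) and beta (P, K-1)"
        )
    eta = X @ beta
    if Z is not None and U is not None:
        Z = np.asarray(Z, dtype=float)
        U = np.asarray(U, dtype=float)
        if Z.shape[0] != X.shape[0] or Z.shape[1] != U.shape[0]                 or U.shape[1] != beta.shape[1]:
            raise ValueError(
                f"shape mismatch: Z is {Z.shape}, U is {U.shape}; "
                f"expected Z (N, N_s) and U (N_s, {beta.shape[1]})"
            )
        eta = eta + Z @ U
    return eta


def precision_predictor(D, theta) -> np.ndarray:
    """Per-observation precision ``exp(D @ theta)`` (always positive)."""
    D = np.asarray(D, dtype=float)
    theta = np.asarray(theta, dtype=float)
    if D.ndim != 2 or D.shape[1] != theta.shape[0]:
        raise ValueError(
            f"shape mismatch: D is {D.shape}, theta has length {theta.size}"
        )
    return np.exp(D @ theta)


def predict_random_effects(fit: DirichletMultinomialMixedModel) -> np.ndarray:
    """Posterior-mode patient intercepts of a fitted random-effect variant."""
    fit._check_fitted()
    if fit.random_effects_ is None:
        raise ValueError(
            f"variant {fit.variant!r} has no random effects (or the inner "
            "optimisation failed)"
        )
    return fit.random_effects_
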