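"""Laplace-approximated marginal likelihood: oracles, limits, separability."""

import numpy as np
import pytest

from compdm import (ModelSimConfig, ModelSpec, build_design, dm_logpmf,
                    joint_nll, laplace_marginal_nll, simulate_from_model)
from compdm.model import _LaplaceEngine, _softmax_ref_last

_LOG2PI = np.log(2 * np.pi)


def _pack(engine, beta, theta, re_params):
    return np.concatenate([np.ravel(beta), np.ravel(theta), np.ravel(re_params)])


@pytest.fixture(scope="module")
def k2_problem():
    """Small K=2 matched dataset with scalar per-patient intercepts."""
    cfg = ModelSimConfig(
        n_patients=5, K=2, seed=3,
        beta=np.array([[0.4], [-0.3]]),
        re_sd=0.5, totals=2000,
        theta_lambda=(np.log(1000.0), -0.1),
    )
    data, _ = simulate_from_model(cfg, "diagREDM")
    data = data.sort_normalised().validate()
    design = build_design(data)
    return data, design


def gauss_hermite_marginal_nll(data, design, beta, theta, log_sd, nodes=61):
    """Independent 1-D adaptive Gauss-Hermite oracle for the K=2 model.

    Integrates each patient's random intercept numerically, centering the
    rule at the integrand's mode with curvature-based scaling.
    """
    from scipy.optimize import minimize_scalar

    t_nodes, w = np.polynomial.hermite.hermgauss(nodes)
    sigma2 = np.exp(2 * log_sd)
    lam = np.exp(design.D @ theta)
    Xbeta = design.X @ beta
    pat = design.patient_index
    total = 0.0
    for i in range(design.n_patients):
        rows = np.where(pat == i)[0]

        def f(u):
            eta = Xbeta[rows] + u
            p = _softmax_ref_last(eta)
            ll = dm_logpmf(data.Y[rows], lam[rows, None] * p)
            return -ll.sum() + 0.5 * u**2 / sigma2 + 0.5 * np.log(2 * np.pi * sigma2)

        mode = minimize_scalar(f, bounds=(-10, 10), method="bounded",
                               options={"xatol": 1e-12}).x
        h = 1e-4
        curv = (f(mode + h) - 2 * f(mode) + f(mode - h)) / h**2
        scale = np.sqrt(2.0 / curv)
        fm = f(mode)
        vals = np.array([f(mode + scale * t) for t in t_nodes])
        integral = scale * np.sum(w * np.exp(t_nodes**2 - (vals - fm)))
        total += fm - np.log(integral)
    return total


def test_laplace_matches_gauss_hermite_quadrature(k2_problem):
    data, design = k2_problem
    spec = ModelSpec("diagREDM")
    eng = _LaplaceEngine(data.Y, design, spec)
    beta = np.array([[0.3], [-0.2]])
    theta = np.array([np.log(1000.0), -0.1])
    log_sd = np.array([np.log(0.5)])
    x = _pack(eng, beta, theta, log_sd)
    lap, _ = laplace_marginal_nll(x, data, design, spec)
    oracle = gauss_hermite_marginal_nll(data, design, beta, theta, log_sd[0])
    assert abs(lap - oracle) / abs(oracle) < 1e-4


def test_zero_variance_limit_reduces_to_joint_at_zero(k2_problem):
    """Sigma -> 0: the marginal NLL collapses to the fixed-effect NLL."""
    data, design = k2_problem
    spec = ModelSpec("diagREDM")
    eng = _LaplaceEngine(data.Y, design, spec)
    beta = np.array([[0.3], [-0.2]])
    theta = np.array([np.log(40.0), -0.3])
    x = _pack(eng, beta, theta, np.array([-20.0]))
    lap, U_hat = laplace_marginal_nll(x, data, design, spec)
    # no-random-effect reference: plain DM regression NLL at U = 0
    lam = np.exp(design.D @ theta)
    p = _softmax_ref_last(design.X @ beta)
    ref = -dm_logpmf(data.Y, lam[:, None] * p).sum()
    assert lap == pytest.approx(ref, abs=1e-6)
    assert np.abs(U_hat).max() < 1e-6  # shrinkage to the prior mean


def test_per_patient_separability(k2_problem):
    """The marginal NLL is the sum of independent per-patient contributions."""
    from compdm.data import DesignSet, ExposureData

    data, design = k2_problem
    spec = ModelSpec("diagREDM")
    eng = _LaplaceEngine(data.Y, design, spec)
    beta = np.array([[0.3], [-0.2]])
    theta = np.array([np.log(40.0), -0.3])
    log_sd = np.array([np.log(0.7)])
    x = _pack(eng, beta, theta, log_sd)
    full, _ = laplace_marginal_nll(x, data, design, spec)
    parts = 0.0
    pat = design.patient_index
    for i in range(design.n_patients):
        rows = np.where(pat == i)[0]
        sub = ExposureData(data.Y[rows], data.patient_id[rows],
                           data.group[rows], list(data.signature_names))
        subdesign = DesignSet(X=design.X[rows], Z=np.ones((len(rows), 1)),
                              D=design.D[rows])
        sub_eng = _LaplaceEngine(sub.Y, subdesign, spec)
        parts += sub_eng.marginal_nll(x)
    assert full == pytest.approx(parts, abs=1e-8)


class TestJointNLL:
    def test_no_re_variant_equals_plain_dm_nll(self, k2_problem):
        data, design = k2_problem
        spec = ModelSpec("FEDMsinglelambda")
        beta = np.array([[0.3], [-0.2]])
        theta = np.array([np.log(40.0)])
        lam = np.full(data.n_obs, np.exp(theta[0]))
        p = _softmax_ref_last(design.X @ beta)
        expected = -dm_logpmf(data.Y, lam[:, None] * p).sum()
        got = joint_nll(beta, theta, None, None, data, design, spec)
        assert got == pytest.approx(expected, abs=1e-9)

    def test_mvn_constant_at_zero_intercepts(self, k2_problem):
        """U = 0, Sigma = I adds exactly N_s*(K-1)/2*log(2pi) to the DM part."""
        data, design = k2_problem
        spec = ModelSpec("diagREDM")
        beta = np.array([[0.3], [-0.2]])
        theta = np.array([np.log(40.0), -0.3])
        Ns = design.n_patients
        U = np.zeros((Ns, 1))
        got = joint_nll(beta, theta, np.eye(1), U, data, design, spec)
        lam = np.exp(design.D @ theta)
        p = _softmax_ref_last(design.X @ beta)
        dm_part = -dm_logpmf(data.Y, lam[:, None] * p).sum()
        assert got - dm_part == pytest.approx(Ns * 0.5 * _LOG2PI, abs=1e-9)

    def test_row_separability_of_the_count_term(self, k2_problem):
        """Doubling one row's counts changes only that row's DM contribution."""
        from compdm.data import ExposureData

        data, design = k2_problem
        spec = ModelSpec("diagREDM")
        beta = np.array([[0.3], [-0.2]])
        theta = np.array([np.log(40.0), -0.3])
        U = np.full((design.n_patients, 1), 0.1)
        base = joint_nll(beta, theta, np.eye(1), U, data, design, spec)
        Y2 = data.Y.copy()
        Y2[0] *= 2
        data2 = ExposureData(Y2, data.patient_id, data.group,
                             list(data.signature_names))
        changed = joint_nll(beta, theta, np.eye(1), U, data2, design, spec)
        lam = np.exp(design.D @ theta)
        eta = design.X @ beta + U[design.patient_index]
        p = _softmax_ref_last(eta)
        delta_row0 = (dm_logpmf(data.Y[0], lam[0] * p[0])
                      - dm_logpmf(Y2[0], lam[0] * p[0]))
        assert changed - base == pytest.approx(delta_row0, abs=1e-9)

    def test_non_pd_sigma_rejected(self, k2_problem):
        data, design = k2_problem
        spec = ModelSpec("diagREDM")
        with pytest.raises(ValueError, match="positive definite"):
            joint_nll(np.array([[0.3], [-0.2]]), np.array([np.log(40.0), 0.0]),
                      np.array([[-1.0]]), np.zeros((design.n_patients, 1)),
                      data, design, spec)


def test_inner_path_descends(small_diag_fit):
    """Accepted outer iterates never increase the marginal NLL (line search)."""
    path = np.array(small_diag_fit.nll_path_)
    assert len(path) >= 2
    assert np.all(np.diff(path) <= 1e-6 * np.maximum(1.0, np.abs(path[:-1])))
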