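"""Estimator behaviour: oracles, recovery, invariance, degenerate inputs."""

import numpy as np
import pytest
from scipy import stats

from compdm import (ExposureData, ModelSimConfig, fit_model,
                    predict_random_effects, simulate_from_model, wald_test)
from compdm.model import DirichletMultinomialMixedModel


def test_k2_fit_matches_betabinomial_grid_mle():
    """Intercept-only K=2, no RE, single precision vs an independent 2-D
    grid search of the beta-binomial likelihood."""
    rng = np.random.default_rng(10)
    N, T = 80, 400
    p_true, lam_true = 0.62, 60.0
    y1 = stats.betabinom.rvs(T, lam_true * p_true, lam_true * (1 - p_true),
                             size=N, random_state=rng)
    Y = np.column_stack([y1, T - y1])
    X = np.ones((N, 1))
    est = DirichletMultinomialMixedModel(variant="FEDMsinglelambda",
                                         compute_vcov=False)
    est.fit(X, Y)
    b0_hat = est.coef_[0, 0]
    loglam_hat = est.precision_coef_[0]

    b0_grid = np.linspace(b0_hat - 0.2, b0_hat + 0.2, 81)
    ll_grid = np.linspace(loglam_hat - 0.5, loglam_hat + 0.5, 81)
    best, arg = -np.inf, None
    for b0 in b0_grid:
        p = np.exp(b0) / (1 + np.exp(b0))
        for ll in ll_grid:
            lam = np.exp(ll)
            val = stats.betabinom.logpmf(y1, T, lam * p, lam * (1 - p)).sum()
            if val > best:
                best, arg = val, (b0, ll)
    assert abs(b0_hat - arg[0]) <= (b0_grid[1] - b0_grid[0])
    assert abs(loglam_hat - arg[1]) <= (ll_grid[1] - ll_grid[0])
    # and our optimum is at least as good as the best grid point
    assert -est.nll_ >= best - 1e-6


def test_fixed_effect_recovery_large_sample():
    """No-RE variant at N=500, T=10^4 recovers beta within ~3 SEs."""
    beta = np.array([[0.8, -0.4], [0.5, -0.5]])
    cfg = ModelSimConfig(n_patients=250, K=3, beta=beta,
                         theta_lambda=(np.log(80.0),), totals=10_000, seed=21)
    data, _ = simulate_from_model(cfg, "FEDMsinglelambda")
    fit = fit_model(data, variant="FEDMsinglelambda")
    assert fit.converged_
    for row in (0, 1):
        se = fit.beta_se(row)
        assert np.all(np.abs(fit.coef_[row] - beta[row]) < 4 * se)


def test_baseline_invariance_under_category_permutation(small_diag_data):
    """Permuting categories while tracking the same reference signature
    leaves the maximised NLL and Wald statistic unchanged."""
    _, data, _ = small_diag_data
    perm = [2, 0, 3, 1]
    data_p = ExposureData(data.Y[:, perm], data.patient_id, data.group,
                          [data.signature_names[k] for k in perm])
    f1 = fit_model(data, variant="diagREDM")
    f2 = fit_model(data_p, variant="diagREDM",
                   ref_category=data_p.signature_names.index("S4"))
    assert abs(f1.nll_ - f2.nll_) < 1e-6
    assert abs(wald_test(f1).w - wald_test(f2).w) < 1e-4


def test_baseline_invariance_across_reference_signatures():
    """For the fixed-effects DM the fit is invariant to the ALR baseline."""
    cfg = ModelSimConfig(n_patients=30, K=3, seed=5)
    data, _ = simulate_from_model(cfg, "FEDMsinglelambda")
    f1 = fit_model(data, variant="FEDMsinglelambda")
    f2 = fit_model(data, variant="FEDMsinglelambda", ref_category=0)
    assert abs(f1.nll_ - f2.nll_) < 1e-6
    assert abs(wald_test(f1).w - wald_test(f2).w) < 1e-4


def test_random_effect_recovery_high_information():
    """Large totals and large RE variance: predicted intercepts track truth."""
    cfg = ModelSimConfig(n_patients=60, K=3, re_sd=1.0, totals=5000,
                         theta_lambda=(np.log(200.0), 0.0), seed=33)
    data, U_true = simulate_from_model(cfg, "diagREDM")
    fit = fit_model(data, variant="diagREDM", compute_vcov=False)
    U_hat = predict_random_effects(fit)
    for k in range(2):
        assert np.corrcoef(U_hat[:, k], U_true[:, k])[0, 1] > 0.9


def test_predict_random_effects_unsupported_variant():
    cfg = ModelSimConfig(n_patients=10, K=3, seed=2)
    data, _ = simulate_from_model(cfg, "FEDMsinglelambda")
    fit = fit_model(data, variant="FEDMsinglelambda", compute_vcov=False)
    with pytest.raises(ValueError, match="random effects"):
        predict_random_effects(fit)


def test_full_covariance_tracks_predicted_intercepts():
    """fullREDM: empirical covariance of predicted intercepts correlates
    with the estimated Sigma entries."""
    corr = np.array([[1.0, 0.6], [0.6, 1.0]])
    cfg = ModelSimConfig(n_patients=80, K=3, re_sd=0.8, re_corr=corr,
                         totals=4000, theta_lambda=(np.log(150.0), 0.0),
                         seed=13)
    data, _ = simulate_from_model(cfg, "fullREDM")
    fit = fit_model(data, variant="fullREDM", compute_vcov=False)
    U_hat = predict_random_effects(fit)
    emp = np.cov(U_hat.T)
    est = fit.covariance_
    pairs = np.corrcoef(emp[np.triu_indices(2)], est[np.triu_indices(2)])[0, 1]
    assert pairs > 0.5
    assert fit.correlation_()[0, 1] > 0.2  # positive dependence recovered


def test_bias_shrinks_with_sample_size():
    """3-point consistency ladder for the group-shift estimates."""
    from compdm.simulate import monte_carlo_study

    rmse = []
    for Ns in (25, 400):
        cfg = ModelSimConfig(n_patients=Ns, K=3, totals=1000, seed=0)
        rep = monte_carlo_study(cfg, variant="diagREDM", n_reps=12, seed=77)
        truth = cfg.resolved_beta()[1]
        err = rep.estimates - truth
        rmse.append(float(np.sqrt((err ** 2).mean())))
    assert rmse[-1] < rmse[0]


def test_nonconvergence_is_flagged_not_raised():
    """Overparameterised fit on tiny data reports converged=False."""
    rng = np.random.default_rng(0)
    Ns, K = 5, 6
    Y = rng.integers(0, 6, size=(2 * Ns, K))
    Y[:, -1] += 1
    data = ExposureData(Y, np.repeat([f"P{i}" for i in range(Ns)], 2),
                        np.tile(["clonal", "subclonal"], Ns))
    fit = fit_model(data, variant="fullREDM", outer_max_iter=40, polish=False)
    assert fit.converged_ is False
    assert fit.vcov_ is None


def test_shape_mismatch_reports_dimensions():
    est = DirichletMultinomialMixedModel()
    with pytest.raises(ValueError, match="conformability"):
        est.fit(np.ones((4, 2)), np.ones((5, 3), dtype=int))


def test_zero_column_rejected_at_load():
    Y = np.array([[5, 0, 3], [2, 0, 4], [1, 0, 2], [3, 0, 3]])
    data = ExposureData(Y, ["P1", "P1", "P2", "P2"],
                        ["clonal", "subclonal"] * 2)
    with pytest.raises(ValueError, match="zero in all observations"):
        data.validate()
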