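import numpy as np
import pytest

from compdm import ModelSimConfig, simulate_from_model
from compdm.data import ModelSpec
from compdm.model import DirichletMultinomialMixedModel, _Layout


@pytest.fixture(scope="session")
def small_diag_data():
    """A 40-patient, 4-signature matched dataset from the diagonal-RE model."""
    cfg = ModelSimConfig(n_patients=40, K=4, seed=11)
    data, U = simulate_from_model(cfg, "diagREDM")
    return cfg, data, U


@pytest.fixture(scope="session")
def small_diag_fit(small_diag_data):
    from compdm import fit_model

    _, data, _ = small_diag_data
    return fit_model(data, variant="diagREDM")


def make_stub_fit(beta, vcov, variant="diagREDM", theta=None):
    """A hand-assembled fitted model for unit-testing inference formulas."""
    beta = np.asarray(beta, dtype=float)
    P, Km1 = beta.shape
    K = Km1 + 1
    est = DirichletMultinomialMixedModel(variant=variant)
    lay = _Layout(P=P, K=K, Q=2, n_patients=2, spec=ModelSpec(variant))
    est.layout_ = lay
    est.param_slices_ = lay.slices
    est.coef_ = beta
    est.precision_coef_ = np.zeros(lay.n_theta) if theta is None else np.asarray(theta, float)
    est.re_params_ = np.zeros(lay.n_re)
    est.vcov_ = np.asarray(vcov, dtype=float)
    est.nll_ = 0.0
    est.converged_ = True
    est.signature_names_ = [f"S{k + 1}" for k in range(K)]
    return est
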