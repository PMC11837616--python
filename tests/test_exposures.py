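"""QP exposure extraction, count rounding and binomial downsampling."""

import numpy as np
import pytest

from compdm import MutationCatalog, SignatureCatalog, downsample_counts
from compdm.exposures import (extract_exposures, extract_proportions,
                              largest_remainder_round)
from compdm.simulate import synthetic_signature_catalog


def _exact_catalog():
    """Rational signature matrix so integer counts can hit S@e exactly."""
    S = np.array([
        [0.5, 0.0],
        [0.5, 0.0],
        [0.0, 0.25],
        [0.0, 0.75],
    ])
    cats = [f"C{i}" for i in range(4)]
    return SignatureCatalog(S, cats, ["sigA", "sigB"])


def test_noiseless_recovery_exact():
    sigs = _exact_catalog()
    e = np.array([0.25, 0.75])
    T = 400
    v = (T * sigs.S @ e).astype(np.int64)
    assert v.sum() == T  # construction is exact
    cat = MutationCatalog(v[:, None], sigs.category_names,
                          np.array(["P1"]), np.array(["clonal"]))
    prop = extract_proportions(cat, sigs)[0]
    np.testing.assert_allclose(prop, e, atol=1e-8)
    data = extract_exposures(cat, sigs)
    assert data.Y[0].sum() == T
    np.testing.assert_array_equal(data.Y[0], [100, 300])


def test_single_active_signature_takes_all_counts():
    sigs = _exact_catalog()
    v = np.array([10, 10, 0, 0])
    cat = MutationCatalog(v[:, None], sigs.category_names,
                          np.array(["P1"]), np.array(["clonal"]))
    data = extract_exposures(cat, sigs, active=["sigA"])
    np.testing.assert_array_equal(data.Y[0], [20])


def test_orthogonal_split_recovers_proportions():
    sigs = _exact_catalog()  # disjoint supports
    # 280 mutations in sigA's support, 120 in sigB's, each matching the
    # signature's internal profile exactly -> 70/30 split
    v = np.array([140, 140, 30, 90])
    cat = MutationCatalog(v[:, None], sigs.category_names,
                          np.array(["P1"]), np.array(["clonal"]))
    prop = extract_proportions(cat, sigs)[0]
    assert prop[0] == pytest.approx(0.7, abs=1e-6)
    assert prop[1] == pytest.approx(0.3, abs=1e-6)


def test_solution_beats_simplex_vertices():
    """QP objective at the solution <= objective at every vertex."""
    rng = np.random.default_rng(8)
    sigs = synthetic_signature_catalog(4, 30, seed=1)
    e = rng.dirichlet(np.ones(4))
    T = 5000
    v = rng.multinomial(T, sigs.S @ e)
    cat = MutationCatalog(v[:, None], sigs.category_names,
                          np.array(["P1"]), np.array(["clonal"]))
    sol = extract_proportions(cat, sigs)[0]
    target = v / T
    obj_sol = np.sum((target - sigs.S @ sol) ** 2)
    for k in range(4):
        vert = np.zeros(4)
        vert[k] = 1.0
        assert obj_sol <= np.sum((target - sigs.S @ vert) ** 2) + 1e-12


def test_recovery_error_vanishes_with_total():
    rng = np.random.default_rng(5)
    sigs = synthetic_signature_catalog(5, 96, seed=2)
    e = rng.dirichlet(np.ones(5) * 2)
    errs = []
    for T in (1000, 100_000):
        v = rng.multinomial(T, sigs.S @ e)
        cat = MutationCatalog(v[:, None], sigs.category_names,
                              np.array(["P1"]), np.array(["clonal"]))
        errs.append(np.abs(extract_proportions(cat, sigs)[0] - e).max())
    assert errs[1] < errs[0]


@pytest.mark.parametrize(
    "e, total, expected",
    [
        ([0.5, 0.5], 3, [2, 1]),            # tie broken by order, sum exact
        ([0.334, 0.333, 0.333], 10, [4, 3, 3]),
        ([1.0, 0.0], 7, [7, 0]),
    ],
)
def test_largest_remainder_rounding(e, total, expected):
    out = largest_remainder_round(np.array(e), total)
    assert out.sum() == total
    np.testing.assert_array_equal(out, expected)


def test_rounded_exposures_always_sum_to_totals():
    rng = np.random.default_rng(3)
    sigs = synthetic_signature_catalog(6, 96, seed=0)
    N = 20
    V = rng.multinomial(777, rng.dirichlet(np.ones(96)), size=N).T
    cat = MutationCatalog(V, sigs.category_names,
                          np.array([f"P{i}" for i in range(N)]),
                          np.array(["clonal"] * N))
    data = extract_exposures(cat, sigs)
    np.testing.assert_array_equal(data.Y.sum(axis=1), V.sum(axis=0))


def test_category_mismatch_rejected():
    sigs = _exact_catalog()
    cat = MutationCatalog(np.ones((3, 1), dtype=int), ["C0", "C1", "C2"],
                          np.array(["P1"]), np.array(["clonal"]))
    with pytest.raises(ValueError, match="categories"):
        extract_exposures(cat, sigs)


class TestDownsample:
    def _data(self):
        from compdm import ExposureData

        Y = np.array([[100, 200, 300], [50, 60, 70], [10, 20, 30], [5, 5, 5]])
        return ExposureData(Y, ["P1", "P1", "P2", "P2"],
                            ["clonal", "subclonal"] * 2)

    def test_identity_at_fraction_one(self):
        d = self._data()
        assert downsample_counts(d, 1.0) is d

    def test_seeded_reproducibility(self):
        d = self._data()
        a = downsample_counts(d, 0.5, seed=9)
        b = downsample_counts(d, 0.5, seed=9)
        np.testing.assert_array_equal(a.Y, b.Y)
        assert a.Y.sum() != d.Y.sum()

    def test_thinning_moments(self):
        d = self._data()
        frac = 0.5
        totals = [downsample_counts(d, frac, seed=s).Y.sum() for s in range(40)]
        T0 = d.Y.sum()
        sd = np.sqrt(T0 * frac * (1 - frac))
        assert abs(np.mean(totals) - frac * T0) < 3 * sd / np.sqrt(40)

    @pytest.mark.parametrize("frac", [0.0, -0.2, 1.5])
    def test_fraction_domain(self, frac):
        with pytest.raises(ValueError):
            downsample_counts(self._data(), frac)

    def test_catalog_thinning(self):
        sigs = _exact_catalog()
        cat = MutationCatalog(np.full((4, 2), 50), sigs.category_names,
                              np.array(["P1", "P1"]),
                              np.array(["clonal", "subclonal"]))
        out = downsample_counts(cat, 0.4, seed=0)
        assert isinstance(out, MutationCatalog)
        assert out.V.sum() < cat.V.sum()
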