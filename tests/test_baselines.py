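"""GMM joint-mark-intensity baseline and the comparison harness."""

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import quad

from mppvae.baselines import (GMMBinTermProvider, GMMIntensity, gmm_fit,
                              gmm_ground_intensity, gmm_intensity, gmm_loglik,
                              holm_sidak_adjust, wilcoxon_holm_sidak)
from mppvae.core_data import BinnedDataset


@pytest.fixture
def one_component():
    return GMMIntensity(lambdas=[2.0], mu_x=[[0.5, -0.5]], prec_x=[[2.0, 1.0]],
                        mu_k=[[1.0]], prec_k=[[4.0]])


class TestIntensityForms:
    def test_mode_evaluation(self, one_component):
        g = one_component
        peak = 2.0 * np.sqrt(2.0 * 1.0) / (2 * np.pi) * np.sqrt(4.0 / (2 * np.pi))
        got = gmm_intensity(g, [0.5, -0.5], [1.0])
        assert got == pytest.approx(peak, rel=1e-12)

    def test_kappa_marginal_matches_quadrature(self, rng):
        g = GMMIntensity(lambdas=[1.5, 0.7], mu_x=[[0.0], [1.0]],
                         prec_x=[[1.0], [2.0]], mu_k=[[0.5], [-1.0]],
                         prec_k=[[2.0], [0.5]])
        for x in ([0.3], [-1.2]):
            num, _ = quad(lambda k: gmm_intensity(g, x, [k]), -30, 30, limit=200)
            assert num == pytest.approx(gmm_ground_intensity(g, x), rel=1e-3)

    def test_scaling_linearity(self, one_component, rng):
        g = one_component
        x, k = rng.standard_normal(2), rng.standard_normal(1)
        g2 = GMMIntensity(2 * g.lambdas, g.mu_x, g.prec_x, g.mu_k, g.prec_k)
        assert gmm_intensity(g2, x, k) == pytest.approx(2 * gmm_intensity(g, x, k))
        assert gmm_ground_intensity(g2, x) == pytest.approx(2 * gmm_ground_intensity(g, x))

    def test_shape_mismatch(self, one_component):
        with pytest.raises(ValueError):
            gmm_intensity(one_component, np.zeros((2, 2)), np.zeros((3, 1)))

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            GMMIntensity([0.0], [[0.0]], [[1.0]], [[0.0]], [[1.0]])


class TestFit:
    def test_zero_iterations_returns_initialization(self, rng):
        xs, ks = rng.standard_normal((30, 2)), rng.standard_normal((30, 3))
        xg = rng.standard_normal((100, 2))
        g0, _ = gmm_fit(xs, ks, xg, n_components=2, n_iter=0, seed=0)
        g1, _ = gmm_fit(xs, ks, xg, n_components=2, n_iter=0, seed=0)
        np.testing.assert_array_equal(g0.mu_k, g1.mu_k)

    def test_objective_trace_increases(self, rng):
        xs, ks = rng.standard_normal((80, 2)), rng.standard_normal((80, 2))
        xg = rng.standard_normal((200, 2))
        _, trace = gmm_fit(xs, ks, xg, n_components=3, n_iter=150, dt=0.05, seed=1)
        assert trace[-1] > trace[0]

    def test_one_component_parameter_recovery(self, rng):
        # data generated from the model itself: per-bin Poisson counts with
        # rate dt * lambda(x_j), marks from the component's mark Gaussian
        true = GMMIntensity([60.0], [[1.0, -1.0]], [[1.0, 1.0]], [[2.0]], [[4.0]])
        dt = 0.05
        xg = rng.standard_normal((4000, 2)) * 1.5
        rates = dt * gmm_ground_intensity(true, xg)
        counts = rng.poisson(rates)
        xs = np.repeat(xg, counts, axis=0)
        n = len(xs)
        ks = true.mu_k[0] + rng.standard_normal((n, 1)) / np.sqrt(true.prec_k[0])
        g, _ = gmm_fit(xs, ks, xg, n_components=1, dt=dt, n_iter=500, lr=0.05, seed=0)
        assert n > 300
        np.testing.assert_allclose(g.mu_x[0], true.mu_x[0], atol=0.15)
        np.testing.assert_allclose(g.mu_k[0], true.mu_k[0], atol=0.1)
        assert g.lambdas[0] == pytest.approx(60.0, rel=0.15)

    def test_homogeneous_rate_recovery(self, rng):
        # flat data: fitted ground-intensity integral ~ n / total_time
        n, m, dt = 300, 1000, 0.1
        xs = rng.standard_normal((n, 1)) * 0.3
        ks = rng.standard_normal((n, 1)) * 0.3
        xg = rng.standard_normal((m, 1)) * 0.3
        g, _ = gmm_fit(xs, ks, xg, n_components=1, dt=dt, n_iter=400, seed=0)
        integral = dt * float(np.sum(gmm_ground_intensity(g, xg)))
        assert integral == pytest.approx(n, rel=0.1)


class TestGMMDecodeTerms:
    def test_exact_value_and_concavity(self, rng):
        g = GMMIntensity(lambdas=[1.0, 2.0], mu_x=[[0.0, 0.0], [1.0, -1.0]],
                         prec_x=[[1.0, 2.0], [0.5, 1.0]],
                         mu_k=[[0.0], [1.0]], prec_k=[[1.0], [1.0]])
        data = BinnedDataset(0.02, 3, np.zeros((3, 2)),
                             [rng.standard_normal((n, 1)) for n in (2, 0, 1)])
        prov = GMMBinTermProvider(g, data)
        xb = rng.standard_normal((3, 2))
        terms = prov.expand(xb, rng)
        for r in range(3):
            # exact per-bin objective: sum_i log lambda(x, k_i) - dt*lambda(x)
            x_eval = xb[r] + 0.3
            direct = -0.02 * gmm_ground_intensity(g, x_eval)
            for k in data.mark_sets[r]:
                direct += np.log(gmm_intensity(g, x_eval, k))
            got = sum(t.exact_value(x_eval) for t in terms[r])
            assert got == pytest.approx(direct, rel=1e-9)
            for t in terms[r]:
                assert np.linalg.eigvalsh(t.hess(x_eval)).max() <= 1e-8


class TestComparisonHarness:
    def test_identical_columns_give_p_one(self, rng):
        col = rng.standard_normal(8)
        df = pd.DataFrame({"A": col, "B": col})
        out = wilcoxon_holm_sidak(df)
        assert out["p_raw"].iloc[0] == 1.0
        assert out["p_adjusted"].iloc[0] == 1.0

    def test_holm_sidak_formula_instantiation(self):
        adj = holm_sidak_adjust([0.01, 0.04])
        assert adj[0] == pytest.approx(1 - 0.99 ** 2)     # 0.0199
        assert adj[1] == pytest.approx(0.04)

    def test_statsmodels_path_agrees_with_formula(self, rng):
        from statsmodels.stats.multitest import multipletests
        p = rng.uniform(0, 0.5, 6)
        np.testing.assert_allclose(holm_sidak_adjust(p),
                                   multipletests(p, method="holm-sidak")[1], rtol=1e-10)

    def test_adjusted_dominates_raw(self, rng):
        p = rng.uniform(size=10)
        adj = holm_sidak_adjust(p)
        assert np.all(adj >= p - 1e-12)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)

    def test_detects_shifted_pair(self, rng):
        base = rng.standard_normal(12)
        df = pd.DataFrame({"A": base, "B": base + 2.0, "C": base + rng.normal(0, 0.01, 12)})
        out = wilcoxon_holm_sidak(df)
        ab = out[(out.model_a == "A") & (out.model_b == "B")].iloc[0]
        assert ab.p_adjusted < 0.05 and ab.significant

    def test_missing_entries_rejected(self):
        df = pd.DataFrame({"A": [1.0, 2, 3, 4, 5], "B": [1.0, np.nan, 3, 4, 5]})
        with pytest.raises(ValueError):
            wilcoxon_holm_sidak(df)

    def test_requires_five_pairs(self):
        df = pd.DataFrame({"A": [1.0, 2, 3], "B": [2.0, 3, 4]})
        with pytest.raises(ValueError):
            wilcoxon_holm_sidak(df)


def test_gmm_loglik_is_exact_reference(rng, one_component=None):
    g = GMMIntensity([2.0], [[0.0]], [[1.0]], [[0.0]], [[1.0]])
    xs, ks = rng.standard_normal((5, 1)), rng.standard_normal((5, 1))
    xg = rng.standard_normal((7, 1))
    direct = sum(np.log(gmm_intensity(g, x, k)) for x, k in zip(xs, ks)) \
        - 0.1 * sum(gmm_ground_intensity(g, x) for x in xg)
    assert gmm_loglik(g, xs, ks, xg, dt=0.1) == pytest.approx(direct, rel=1e-10)
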