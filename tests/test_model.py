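"""Unit tests for the scaled-Poisson quasi-likelihood and E/M blocks."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import minimize, minimize_scalar
from scipy.stats import poisson

from prism import (
    ValidationError,
    expected_allocation,
    joint_loglik,
    m_step_composition,
    m_step_expression,
    m_step_precision,
    scaled_poisson_loglik,
    scaled_poisson_logpdf,
    CountMatrix,
    ModelParams,
)
from prism.simulate import sample_scaled_poisson


class TestScaledPoissonLoglik:
    @pytest.mark.parametrize(
        "z, lam, t, expected",
        [
            (0.0, 1.0, 1.0, -1.0),  # Poisson log-pmf at zero
            (2.0, 2.0, 1.0, 2 * math.log(2) - 2 - math.log(2)),
            # hand-evaluated: 2*1*log(2*1) - 2*1 - lgamma(2*1+1)
            (1.0, 1.0, 2.0, 2 * math.log(2) - 2 - math.lgamma(3)),
            (0.0, 0.0, 1.0, 0.0),  # point mass at zero
        ],
    )
    def test_pinned_values(self, z, lam, t, expected):
        assert scaled_poisson_loglik(z, lam, t) == pytest.approx(
            expected, abs=1e-12
        )

    def test_zero_mean_positive_count_is_impossible(self):
        assert scaled_poisson_loglik(1.0, 0.0, 1.0) == -np.inf

    def test_matches_poisson_pmf_at_unit_precision(self):
        z = np.arange(0, 20, dtype=float)
        lam = 3.7
        np.testing.assert_allclose(
            scaled_poisson_loglik(z, lam, 1.0),
            poisson.logpmf(z.astype(int), lam),
            rtol=1e-12,
        )

    @pytest.mark.parametrize("z, lam", [(-1.0, 1.0), (1.0, -2.0)])
    def test_negative_domain_rejected(self, z, lam):
        with pytest.raises(ValidationError):
            scaled_poisson_loglik(z, lam, 1.0)

    def test_precision_bounds_enforced(self):
        with pytest.raises(ValidationError):
            scaled_poisson_loglik(1.0, 1.0, 1e9)

    def test_logpdf_adds_lattice_jacobian(self):
        z, lam, t = 4.0, 3.0, 0.5
        assert scaled_poisson_logpdf(z, lam, t) == pytest.approx(
            math.log(t) + scaled_poisson_loglik(z, lam, t)
        )
        # degenerate point mass carries no jacobian
        assert scaled_poisson_logpdf(0.0, 0.0, 0.5) == 0.0


class TestExpectedAllocation:
    @pytest.mark.parametrize(
        "y, x, w, expected",
        [
            (8.0, [1.0, 3.0], [0.5, 0.5], [2.0, 6.0]),
            (17.0, [5.0], [1.0], [17.0]),
            (0.0, [1.0, 2.0], [0.3, 0.7], [0.0, 0.0]),
        ],
    )
    def test_examples(self, y, x, w, expected):
        np.testing.assert_allclose(
            expected_allocation(y, np.array(x), np.array(w)), expected
        )

    def test_zero_denominator_falls_back_to_composition(self):
        out = expected_allocation(10.0, np.zeros(2), np.array([0.25, 0.75]))
        np.testing.assert_allclose(out, [2.5, 7.5])

    @given(
        y=st.floats(0.0, 1e6),
        x=st.lists(st.floats(0.0, 1e3), min_size=1, max_size=5),
        w_raw=st.lists(st.floats(0.01, 1.0), min_size=1, max_size=5),
        c=st.floats(0.01, 100.0),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_conservation_and_scale_invariance(self, y, x, w_raw, c):
        k = min(len(x), len(w_raw))
        x = np.array(x[:k])
        w = np.array(w_raw[:k])
        w = w / w.sum()
        out = expected_allocation(y, x, w)
        assert out.sum() == pytest.approx(y, abs=1e-9 * max(1.0, y))
        # scale invariance in x, 1-homogeneity in y
        np.testing.assert_allclose(
            expected_allocation(y, c * x, w), out, rtol=1e-9, atol=1e-12
        )
        np.testing.assert_allclose(
            expected_allocation(c * y, x, w), c * out, rtol=1e-9,
            atol=1e-12,
        )

    def test_matches_exact_conditional_by_enumeration(self):
        # for t = 1 the latent counts given their sum are multinomial, so
        # the proportional rule is the exact conditional mean; verify by
        # brute-force lattice enumeration for all y <= 6
        lam = np.array([2.3, 0.9])
        w = np.array([0.4, 0.6])
        x = lam / w  # so that x * w = lam
        for y in range(7):
            z1 = np.arange(y + 1)
            logp = poisson.logpmf(z1, lam[0]) + poisson.logpmf(
                y - z1, lam[1]
            )
            p = np.exp(logp - logp.max())
            p /= p.sum()
            exact = np.array([(z1 * p).sum(), ((y - z1) * p).sum()])
            np.testing.assert_allclose(
                expected_allocation(float(y), x, w), exact, atol=1e-9
            )


class TestJointLoglik:
    def _tiny(self):
        sc = CountMatrix(np.array([[0.0]]), ["g0"], ["c0"], "single_cell")
        bulk = CountMatrix(np.array([[0.0]]), ["g0"], ["b0"], "bulk")
        params = ModelParams(
            X=np.array([[1.0]]), T=np.array([[1.0]]),
            W=np.array([[1.0, 1.0]]), G=np.array([1.0, 1.0]),
        )
        return sc, bulk, params

    def test_single_cell_single_gene_reduces_to_one_term(self):
        sc, bulk, params = self._tiny()
        z = np.zeros((1, 1, 1))
        # two units, each contributing ll(0; 1, 1) = -1
        assert joint_loglik(sc, bulk, params, z, z) == pytest.approx(-2.0)

    def test_agrees_with_explicit_summation(self):
        rng = np.random.default_rng(3)
        m, k, n0, r = 2, 2, 2, 2
        sc = CountMatrix(
            rng.poisson(5, (m, n0)).astype(float),
            ["g0", "g1"], ["c0", "c1"], "single_cell",
        )
        bulk = CountMatrix(
            rng.poisson(9, (m, r)).astype(float), ["g0", "g1"],
            ["b0", "b1"], "bulk",
        )
        X = rng.uniform(1, 5, (m, k))
        T = rng.uniform(0.5, 2.0, (m, k))
        W = rng.dirichlet(np.ones(k), n0 + r).T
        G = rng.uniform(0.5, 2.0, n0 + r)
        params = ModelParams(X, T, W, G)
        z_sc = rng.uniform(0, 4, (m, k, n0))
        z_b = rng.uniform(0, 4, (m, k, r))
        expected = 0.0
        for i in range(m):
            for l in range(k):
                for j in range(n0):
                    expected += scaled_poisson_loglik(
                        z_sc[i, l, j], X[i, l] * W[l, j] * G[j], T[i, l]
                    )
                for s in range(r):
                    expected += scaled_poisson_loglik(
                        z_b[i, l, s],
                        X[i, l] * W[l, n0 + s] * G[n0 + s], T[i, l],
                    )
        got = joint_loglik(sc, bulk, params, z_sc, z_b)
        assert got == pytest.approx(expected, rel=1e-12)
        # invariant under a joint permutation of cell-type indices
        perm = [1, 0]
        params_p = ModelParams(X[:, perm], T[:, perm], W[perm], G)
        got_p = joint_loglik(
            sc, bulk, params_p, z_sc[:, perm], z_b[:, perm]
        )
        assert got_p == pytest.approx(got, rel=1e-12)

    def test_gauge_invariance(self):
        # X -> cX, G -> G/c leaves the likelihood unchanged
        rng = np.random.default_rng(4)
        sc = CountMatrix(
            rng.poisson(5, (3, 2)).astype(float),
            [f"g{i}" for i in range(3)], ["c0", "c1"], "single_cell",
        )
        bulk = CountMatrix(
            rng.poisson(9, (3, 1)).astype(float),
            [f"g{i}" for i in range(3)], ["b0"], "bulk",
        )
        X = rng.uniform(1, 5, (3, 2))
        T = np.ones((3, 2))
        W = rng.dirichlet(np.ones(2), 3).T
        G = rng.uniform(0.5, 2.0, 3)
        z_sc = rng.uniform(0, 4, (3, 2, 2))
        z_b = rng.uniform(0, 4, (3, 2, 1))
        base = joint_loglik(sc, bulk, ModelParams(X, T, W, G), z_sc, z_b)
        for c in (0.1, 3.7):
            scaled = joint_loglik(
                sc, bulk, ModelParams(c * X, T, W, G / c), z_sc, z_b
            )
            assert scaled == pytest.approx(base, rel=1e-10)


class TestMStepExpression:
    def test_weighted_ratio_examples(self):
        # one unit: Z=10, W=1, G=2 -> X = 5
        Z = np.array([[[10.0]]])
        assert m_step_expression(
            Z, np.array([[1.0]]), np.array([2.0])
        )[0, 0] == pytest.approx(5.0)
        # two units Z={4,6}, WG={1,1} -> X = 5
        Z = np.array([[[4.0, 6.0]]])
        assert m_step_expression(
            Z, np.array([[1.0, 1.0]]), np.array([1.0, 1.0])
        )[0, 0] == pytest.approx(5.0)

    def test_zero_denominator_gives_zero(self):
        Z = np.zeros((1, 1, 1))
        X = m_step_expression(Z, np.array([[0.0]]), np.array([1.0]))
        assert X[0, 0] == 0.0

    def test_agrees_with_numeric_maximization(self):
        # golden-section oracle: maximize the quasi-likelihood in one X
        # entry on a random small instance
        rng = np.random.default_rng(7)
        n = 4
        W = rng.dirichlet(np.ones(2), n).T
        G = rng.uniform(0.5, 2.0, n)
        Z = rng.uniform(0.5, 10.0, (1, 2, n))
        t = rng.uniform(0.3, 3.0, (1, 2))
        X = m_step_expression(Z, W, G)
        for l in range(2):
            def neg(x):
                lam = x * W[l] * G
                return -scaled_poisson_loglik(Z[0, l], lam, t[0, l]).sum()
            opt = minimize_scalar(neg, bounds=(1e-6, 100.0),
                                  method="bounded")
            assert X[0, l] == pytest.approx(opt.x, rel=1e-4)


class TestMStepComposition:
    def test_k1_is_always_one(self):
        w, g, flag = m_step_composition(
            np.array([[5.0]]), np.array([[2.0]]), np.array([[1.0]]), 3.0
        )
        np.testing.assert_allclose(w, [1.0])
        assert not flag

    def test_symmetric_profiles_reduce_to_proportions(self):
        # equal X and T columns, allocation totals {30, 10} -> (0.75, 0.25)
        m = 5
        alloc = np.zeros((m, 2))
        alloc[:, 0] = 30.0 / m
        alloc[:, 1] = 10.0 / m
        X = np.ones((m, 2)) * 2.0
        T = np.ones((m, 2))
        w, g_new, flag = m_step_composition(alloc, X, T, 1.0)
        np.testing.assert_allclose(w, [0.75, 0.25], atol=1e-12)
        assert w.sum() == pytest.approx(1.0, abs=1e-12)

    def test_matches_constrained_numeric_maximizer(self):
        rng = np.random.default_rng(9)
        m = 6
        alloc = rng.uniform(0.5, 8.0, (m, 2))
        X = rng.uniform(0.5, 4.0, (m, 2))
        T = rng.uniform(0.5, 2.0, (m, 2))
        w, g_new, _ = m_step_composition(alloc, X, T, 1.0)

        def neg(params):
            w1, g = params
            wv = np.array([w1, 1 - w1])
            lam = X * wv[None, :] * g
            return -scaled_poisson_loglik(alloc, lam, T).sum()

        res = minimize(neg, x0=[0.5, 1.0], method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-12})
        assert w[0] == pytest.approx(res.x[0], abs=1e-5)
        assert g_new == pytest.approx(res.x[1], rel=1e-4)

    def test_all_zero_allocation_flagged_uniform(self):
        w, g, flag = m_step_composition(
            np.zeros((3, 2)), np.ones((3, 2)), np.ones((3, 2)), 2.0
        )
        np.testing.assert_allclose(w, [0.5, 0.5])
        assert flag


class TestMStepPrecision:
    @pytest.mark.parametrize("t_true, tol", [(1.0, 0.1), (0.25, 0.05)])
    def test_recovers_dispersion_at_2000_units(self, t_true, tol):
        rng = np.random.default_rng(21)
        m, n = 40, 2000
        lam = rng.uniform(20, 80, m)
        counts = sample_scaled_poisson(
            rng, np.repeat(lam[:, None], n, axis=1), t_true
        )
        Z = counts[:, None, :]
        means = np.repeat(lam[:, None], n, axis=1)[:, None, :]
        T = m_step_precision(Z, means, np.ones((m, 1)))
        assert np.mean(T) == pytest.approx(t_true, abs=tol)

    def test_zero_variance_clamps_to_t_max(self):
        Z = np.full((1, 1, 5), 4.0)
        means = np.full((1, 1, 5), 4.0)
        T = m_step_precision(Z, means, np.ones((1, 1)))
        assert T[0, 0] == pytest.approx(1e3)

    def test_no_information_keeps_prior(self):
        Z = np.zeros((1, 1, 3))
        means = np.zeros((1, 1, 3))
        T = m_step_precision(Z, means, np.full((1, 1), 0.7))
        assert T[0, 0] == pytest.approx(0.7)
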