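import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import special, stats as sps

from methsig.errors import ParameterError
from methsig.stats import (bh_fdr, diff_score, fit_f_dist, hypergeometric_tail,
                           ihc_total_score, log10_binomial_tail, moderated_t_table,
                           pooled_t_from_summary, welch_t_test)


def hypergeom_tail_exact(N, K, n, k):
    """Enumeration oracle: exact rational upper tail."""
    if k <= max(0, n + K - N):
        return Fraction(1)
    total = Fraction(0)
    for j in range(k, min(K, n) + 1):
        total += Fraction(math.comb(K, j) * math.comb(N - K, n - j), math.comb(N, n))
    return total


class TestHypergeometricTail:
    @pytest.mark.parametrize("N,K,n,k,expected", [
        (10, 5, 4, 4, 5 / 210),        # enumeration of C(10,4) draws
        (100, 10, 10, 0, 1.0),         # tail from zero
        (20, 6, 5, 2, 7496 / 15504),   # 1 - P(0) - P(1)
    ])
    def test_reference_values(self, N, K, n, k, expected):
        res = hypergeometric_tail(N, K, n, k)
        assert res.p_value == pytest.approx(expected, rel=1e-12)

    def test_out_of_support(self):
        assert hypergeometric_tail(10, 5, 4, 5).p_value == 0.0
        assert hypergeometric_tail(10, 5, 4, -1).p_value == 1.0

    def test_parameter_errors(self):
        with pytest.raises(ParameterError):
            hypergeometric_tail(10, 11, 4, 2)
        with pytest.raises(ParameterError):
            hypergeometric_tail(10, 5, 11, 2)

    def test_matches_enumeration_spot_checks(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            N = int(rng.integers(1, 26))
            K = int(rng.integers(0, N + 1))
            n = int(rng.integers(0, N + 1))
            k = int(rng.integers(0, min(K, n) + 1))
            got = hypergeometric_tail(N, K, n, k).p_value
            want = float(hypergeom_tail_exact(N, K, n, k))
            assert got == pytest.approx(want, rel=1e-10)

    def test_matches_scipy_sf(self):
        got = hypergeometric_tail(5000, 900, 400, 110)
        want = sps.hypergeom.sf(109, 5000, 900, 400)
        assert got.p_value == pytest.approx(want, rel=1e-9)


class TestBinomialTail:
    def test_trivial_cases(self):
        assert log10_binomial_tail(10, 0, 0.21).p_value == 1.0
        assert log10_binomial_tail(4, 4, 0.5).p_value == pytest.approx(0.0625, rel=1e-12)

    def test_deep_tail_matches_betainc(self):
        # P(X >= k) = I_p0(k, n-k+1); scipy's regularized incomplete beta
        # is an independent route that stays representable here.
        res = log10_binomial_tail(2961, 1395, 0.21)
        oracle = math.log10(float(special.betainc(1395, 2961 - 1395 + 1, 0.21)))
        assert res.log10_p == pytest.approx(oracle, abs=1e-6)
        assert res.log10_p == pytest.approx(-218.295, abs=0.01)

    def test_kl_upper_bound(self):
        n, p0 = 2961, 0.21
        for k in (700, 1000, 1395, 2000):
            f = k / n
            kl = f * math.log(f / p0) + (1 - f) * math.log((1 - f) / (1 - p0))
            bound = -n * kl / math.log(10)
            assert log10_binomial_tail(n, k, p0).log10_p <= bound + 1e-9

    def test_monotone_in_k(self):
        values = [log10_binomial_tail(300, k, 0.21).log10_p for k in range(0, 301, 10)]
        assert all(a >= b for a, b in zip(values, values[1:]))

    def test_parameter_errors(self):
        with pytest.raises(ParameterError):
            log10_binomial_tail(10, 2, 0.0)
        with pytest.raises(ParameterError):
            log10_binomial_tail(10, 11, 0.5)


def bh_oracle(p):
    """Brute-force step-up: q_(i) = min_{j >= i} m p_(j) / j, capped at 1."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])  # stable: ties by index
    q = [0.0] * m
    for rank, i in enumerate(order, start=1):
        q[i] = min(min(m * p[order[r - 1]] / r for r in range(rank, m + 1)), 1.0)
    return q


class TestBhFdr:
    def test_identity_single(self):
        assert bh_fdr([0.05]) == pytest.approx([0.05])

    def test_step_up_example(self):
        assert bh_fdr([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=12))
    def test_matches_brute_force(self, p):
        got = bh_fdr(p)
        want = bh_oracle(p)
        assert np.allclose(got, want, atol=1e-12)

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=2, max_size=40))
    def test_monotone_and_bounded(self, p):
        q = bh_fdr(p)
        assert np.all(q <= 1.0 + 1e-15)
        order = np.argsort(p, kind="stable")
        assert np.all(np.diff(q[order]) >= -1e-12)
        assert q[order[0]] >= p[order[0]] - 1e-12

    def test_rejects_out_of_range(self):
        with pytest.raises(ParameterError):
            bh_fdr([0.2, 1.3])


class TestWelch:
    def test_identical_groups(self):
        res = welch_t_test([1, 2, 3], [1, 2, 3])
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_reference_value(self):
        res = welch_t_test([1.1, 0.9, 1.0], [2.1, 1.9, 2.0])
        assert res.statistic == pytest.approx(-12.247, abs=5e-3)
        assert res.df == pytest.approx(4.0, abs=1e-6)
        assert res.p_value == pytest.approx(2.552e-4, rel=1e-3)

    def test_constant_groups_flagged_degenerate(self):
        res = welch_t_test([0, 0, 0, 0], [10, 10, 10, 10])
        assert res.degenerate
        assert res.p_value < 1e-10

    @given(st.lists(st.floats(-50, 50), min_size=2, max_size=8),
           st.lists(st.floats(-50, 50), min_size=2, max_size=8))
    def test_antisymmetric_under_swap(self, a, b):
        r1 = welch_t_test(a, b)
        r2 = welch_t_test(b, a)
        assert r1.statistic == pytest.approx(-r2.statistic, abs=1e-9)
        assert r1.p_value == pytest.approx(r2.p_value, abs=1e-12)

    def test_small_group_rejected(self):
        with pytest.raises(ParameterError):
            welch_t_test([1.0], [1.0, 2.0])


class TestPooledTFromSummary:
    def test_equal_summaries(self):
        res = pooled_t_from_summary(8, 5.0, 1.0, 8, 5.0, 1.0)
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_matches_scipy(self):
        mine = pooled_t_from_summary(6, 2.0, 1.5, 9, 3.1, 1.2)
        ref = sps.ttest_ind_from_stats(2.0, 1.5, 6, 3.1, 1.2, 9, equal_var=True)
        assert mine.statistic == pytest.approx(ref.statistic, rel=1e-9)
        assert mine.p_value == pytest.approx(ref.pvalue, rel=1e-9)

    def test_degenerate_equal_means(self):
        res = pooled_t_from_summary(3, 1.0, 0.0, 4, 1.0, 0.0)
        assert res.p_value == 1.0 and res.degenerate


class TestDiffScore:
    def test_threshold_semantics(self):
        assert diff_score(0.3, 0.05) == pytest.approx(13.0103, abs=1e-4)
        assert diff_score(-0.3, 0.001) == pytest.approx(-30.0)
        assert diff_score(0.5, 1.0) == 0.0
        assert diff_score(0.0, 0.01) == 0.0

    def test_crosses_13_at_p_10_to_minus_1p3(self):
        p_star = 10 ** -1.3
        assert diff_score(1.0, p_star) == pytest.approx(13.0)
        assert diff_score(1.0, p_star * 1.01) < 13.0
        assert diff_score(1.0, p_star * 0.99) > 13.0

    def test_rejects_nonpositive_p(self):
        with pytest.raises(ParameterError):
            diff_score(1.0, 0.0)


class TestIhcScore:
    @pytest.mark.parametrize("intensity,proportion,total", [(3, 7, 10), (0, 0, 0), (2, 5, 7)])
    def test_additive(self, intensity, proportion, total):
        assert ihc_total_score(intensity, proportion) == total

    @pytest.mark.parametrize("intensity,proportion", [(4, 0), (-1, 3), (2, 8)])
    def test_range_checks(self, intensity, proportion):
        with pytest.raises(ParameterError):
            ihc_total_score(intensity, proportion)


class TestModeratedT:
    """Cross-check of the empirical-Bayes moderated t against values
    computed with Bioconductor limma (lmFit + eBayes) on this exact
    seeded fixture."""

    LIMMA_D0 = 4.576080
    LIMMA_S0 = 0.214206
    LIMMA_T5 = [-0.373007, 0.474435, -1.167409, -0.121399, -9.758013]
    LIMMA_P5 = [7.1819523e-01, 6.4703633e-01, 2.7447627e-01, 9.0617169e-01, 6.2271658e-06]

    @pytest.fixture()
    def fixture_groups(self):
        rng = np.random.default_rng(20240901)
        n_probes, n1, n2 = 400, 3, 3
        sd = np.exp(rng.normal(-0.7, 0.4, size=n_probes))
        effect = np.where(rng.random(n_probes) < 0.1,
                          rng.normal(0, 2.0, size=n_probes), 0.0)
        a = rng.normal(0, 1, (n_probes, n1)) * sd[:, None] + effect[:, None]
        b = rng.normal(0, 1, (n_probes, n2)) * sd[:, None]
        return a, b

    def test_prior_fit_matches_limma(self, fixture_groups):
        a, b = fixture_groups
        s2 = ((a.shape[1] - 1) * a.var(axis=1, ddof=1)
              + (b.shape[1] - 1) * b.var(axis=1, ddof=1)) / 4.0
        d0, s0 = fit_f_dist(s2, np.full(len(s2), 4.0))
        assert d0 == pytest.approx(self.LIMMA_D0, abs=1e-4)
        assert s0 == pytest.approx(self.LIMMA_S0, abs=1e-4)

    def test_statistics_match_limma(self, fixture_groups):
        a, b = fixture_groups
        n = len(a)
        v1 = a.var(axis=1, ddof=1)
        v2 = b.var(axis=1, ddof=1)
        s2 = (2 * v1 + 2 * v2) / 4.0
        t, p, df = moderated_t_table(a.mean(1) - b.mean(1), s2,
                                     np.full(n, 4.0), np.full(n, 3.0), np.full(n, 3.0))
        assert np.allclose(t[:5], self.LIMMA_T5, atol=1e-5)
        assert np.allclose(p[:5], self.LIMMA_P5, rtol=1e-3)
        assert np.all(df == pytest.approx(4.0 + self.LIMMA_D0, abs=1e-3))

    def test_homoscedastic_prior_df_is_infinite(self):
        rng = np.random.default_rng(5)
        s2 = sps.chi2.rvs(4, size=2000, random_state=rng) / 4.0
        d0, s0 = fit_f_dist(s2, np.full(2000, 4.0))
        assert math.isinf(d0)
        assert s0 == pytest.approx(1.0, abs=0.1)
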