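"""Unit and property tests for the statistical primitives."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from ifomics import stats


# ---------------------------------------------------------------------------
# Benjamini-Hochberg


class TestBHAdjust:
    @pytest.mark.parametrize(
        "pvals, expected",
        [
            ([0.03], [0.03]),                               # m=1: q equals p
            ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),  # hand step-up
            ([1.0, 1.0, 1.0], [1.0, 1.0, 1.0]),
        ],
    )
    def test_known_values(self, pvals, expected):
        assert stats.bh_adjust(pvals) == pytest.approx(expected)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            stats.bh_adjust([0.5, 1.5])
        with pytest.raises(ValueError):
            stats.bh_adjust([-0.1])

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.uniform(size=200)
        q = stats.bh_adjust(p)
        _rej, q_sm, *_ = multipletests(p, method="fdr_bh")
        assert np.allclose(q, q_sm)

    def test_permutation_invariance(self, rng):
        p = rng.uniform(size=50)
        perm = rng.permutation(50)
        q = stats.bh_adjust(p)
        q_perm = stats.bh_adjust(p[perm])
        assert np.allclose(q[perm], q_perm)

    def test_monotone_in_sorted_order(self, rng):
        p = rng.uniform(size=100)
        order = np.argsort(p)
        q = stats.bh_adjust(p)
        assert np.all(np.diff(q[order]) >= -1e-15)


# ---------------------------------------------------------------------------
# Hypergeometric / Fisher


def _hypergeom_enum(N, K, n, k):
    from math import comb

    return sum(comb(K, j) * comb(N - K, n - j) for j in range(k, min(K, n) + 1)) / comb(N, n)


class TestExactTails:
    def test_upper_tail_trivial(self):
        assert stats.hypergeom_upper_tail(20, 5, 8, 0) == 1.0
        assert stats.hypergeom_upper_tail(10, 10, 10, 10) == pytest.approx(1.0)

    def test_upper_tail_enumeration_example(self):
        # C(5,4)C(15,4)/C(20,8) + C(5,5)C(15,3)/C(20,8)
        assert stats.hypergeom_upper_tail(20, 5, 8, 4) == pytest.approx(
            _hypergeom_enum(20, 5, 8, 4), rel=1e-12
        )
        assert stats.hypergeom_upper_tail(20, 5, 8, 4) == pytest.approx(0.0578, abs=5e-4)

    def test_inconsistent_counts(self):
        with pytest.raises(ValueError):
            stats.hypergeom_upper_tail(10, 12, 3, 1)
        with pytest.raises(ValueError):
            stats.hypergeom_upper_tail(10, 5, 3, 4)

    def test_fisher_example_22_over_120(self):
        assert stats.fisher_exact_enrichment([[2, 1], [1, 6]]) == pytest.approx(
            22 / 120, rel=1e-12
        )

    def test_fisher_whole_universe_term(self):
        # every feature in the term: enrichment cannot exceed chance
        assert stats.fisher_exact_enrichment([[5, 0], [5, 0]]) == pytest.approx(1.0)

    def test_fisher_zero_overlap_near_one(self):
        assert stats.fisher_exact_enrichment([[0, 2], [10, 88]]) > 0.95

    def test_fisher_negative_counts(self):
        with pytest.raises(ValueError):
            stats.fisher_exact_enrichment([[1, -1], [0, 2]])

    def test_fisher_equals_hypergeom_exhaustive_small_tables(self):
        # every 2x2 table with N <= 12 against direct enumeration
        for N in range(1, 13):
            for a, b, c in itertools.product(range(N + 1), repeat=3):
                d = N - a - b - c
                if d < 0:
                    continue
                p = stats.fisher_exact_enrichment([[a, b], [c, d]])
                expected = _hypergeom_enum(N, a + b, a + c, a)
                assert p == pytest.approx(expected, rel=1e-10, abs=1e-12)


# ---------------------------------------------------------------------------
# Dunnett


class TestAnovaDunnett:
    def test_single_treatment_equals_pooled_t(self, rng):
        # with one comparison the adjusted p is the two-sided two-sample
        # pooled-t p, up to Monte-Carlo error
        a = rng.normal(0, 1, 6)
        b = rng.normal(0.5, 1, 6)
        res = stats.anova_dunnett({"ctrl": a, "trt": b}, "ctrl", mc_reps=200_000, seed=5)
        t, p = sps.ttest_ind(b, a, equal_var=True)
        assert res[0].t == pytest.approx(t, rel=1e-10)
        assert res[0].p_raw == pytest.approx(p, rel=1e-10)
        assert res[0].p_adjusted == pytest.approx(p, abs=0.01)

    def test_zero_variance_degenerate(self):
        groups = {"ctrl": [1.0, 1.0], "t1": [1.0, 1.0], "t2": [1.0, 1.0]}
        res = stats.anova_dunnett(groups, "ctrl", mc_reps=1000, seed=0)
        assert all(r.p_adjusted == 1.0 and r.degenerate for r in res)

    def test_adjusted_at_least_raw_and_monotone_in_t(self, rng):
        groups = {
            "ctrl": rng.normal(0, 1, 4),
            "t1": rng.normal(0.3, 1, 5),
            "t2": rng.normal(1.5, 1, 5),
            "t3": rng.normal(-0.7, 1, 4),
        }
        res = stats.anova_dunnett(groups, "ctrl", mc_reps=20_000, seed=1)
        for r in res:
            assert r.p_adjusted >= r.p_raw - 1e-12
            assert 0.0 <= r.p_adjusted <= 1.0
        by_t = sorted(res, key=lambda r: abs(r.t))
        adj = [r.p_adjusted for r in by_t]
        assert all(a >= b - 1e-12 for a, b in zip(adj, adj[1:]))

    def test_group_too_small(self):
        with pytest.raises(ValueError):
            stats.anova_dunnett({"ctrl": [1.0, 2.0], "t": [1.0]}, "ctrl")

    def test_matches_scipy_dunnett(self, rng):
        # independent implementation cross-check
        a = rng.normal(0, 1, 5)
        b = rng.normal(0.8, 1, 5)
        c = rng.normal(-0.4, 1, 5)
        res = stats.anova_dunnett(
            {"ctrl": a, "b": b, "c": c}, "ctrl", mc_reps=400_000, seed=3
        )
        ref = sps.dunnett(b, c, control=a)
        ours = {r.comparison.split(" ")[0]: r for r in res}
        assert ours["b"].t == pytest.approx(ref.statistic[0], rel=1e-8)
        assert ours["c"].t == pytest.approx(ref.statistic[1], rel=1e-8)
        assert ours["b"].p_adjusted == pytest.approx(ref.pvalue[0], abs=0.01)
        assert ours["c"].p_adjusted == pytest.approx(ref.pvalue[1], abs=0.01)


# ---------------------------------------------------------------------------
# Grubbs


class TestGrubbs:
    def test_hand_example(self):
        res = stats.grubbs_one_sided_max([1.0, 1.1, 0.9, 5.0], alpha=0.05)
        # mean 2.0, sd 2.00167 -> G = 1.49875, near the n=4 maximum 1.5
        assert res.G == pytest.approx(1.49875, abs=1e-4)
        assert res.index == 3
        assert res.G < 3 / np.sqrt(4) + 1e-9

    def test_all_equal_no_outlier(self):
        res = stats.grubbs_one_sided_max([2.0, 2.0, 2.0, 2.0])
        assert res.p == 1.0 and not res.is_outlier

    def test_too_few_values(self):
        with pytest.raises(ValueError):
            stats.grubbs_one_sided_max([1.0, 2.0])

    @pytest.mark.parametrize("n, alpha", [(10, 0.05), (18, 0.1), (7, 0.01)])
    def test_self_inversion_at_critical_value(self, n, alpha):
        # analytically inverted one-sided critical value reproduces alpha
        t_crit = sps.t.ppf(1 - alpha / n, n - 2)
        g_crit = (n - 1) / np.sqrt(n) * np.sqrt(t_crit**2 / (n - 2 + t_crit**2))
        # construct a sample whose maximum attains exactly G = g_crit
        from scipy.optimize import brentq

        base = np.linspace(-1, 1, n - 1)

        def g_minus_crit(x):
            v = np.append(base, x)
            return (v.max() - v.mean()) / v.std(ddof=1) - g_crit

        x = brentq(g_minus_crit, 1.01, 1e6)
        res = stats.grubbs_one_sided_max(np.append(base, x), alpha=alpha)
        assert res.p == pytest.approx(alpha, abs=1e-6)


# ---------------------------------------------------------------------------
# Mahalanobis


class TestMahalanobis:
    def test_identity_covariance(self):
        d, reg = stats.mahalanobis_distance([3.0, 4.0], [0.0, 0.0], np.eye(2))
        assert d == pytest.approx(5.0) and not reg

    def test_one_dimensional(self):
        d, _ = stats.mahalanobis_distance([7.0], [3.0], [[4.0]])
        assert d == pytest.approx(2.0)

    def test_correlated_2x2_closed_form(self):
        S = np.array([[2.0, 1.2], [1.2, 1.5]])
        x = np.array([1.0, -0.5])
        mu = np.array([0.2, 0.3])
        det = S[0, 0] * S[1, 1] - S[0, 1] ** 2
        inv = np.array([[S[1, 1], -S[0, 1]], [-S[0, 1], S[0, 0]]]) / det
        expected = np.sqrt((x - mu) @ inv @ (x - mu))
        d, reg = stats.mahalanobis_distance(x, mu, S)
        assert d == pytest.approx(expected, rel=1e-12) and not reg

    def test_singular_covariance_regularized(self):
        S = np.array([[1.0, 1.0], [1.0, 1.0]])
        d, reg = stats.mahalanobis_distance([1.0, 0.0], [0.0, 0.0], S)
        assert reg and np.isfinite(d)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            stats.mahalanobis_distance([1.0, 2.0], [0.0], np.eye(2))


# ---------------------------------------------------------------------------
# Position scores


class TestPositionScore1D:
    def test_members_on_top(self):
        values = [1, 2, 3, 10, 11]
        flags = [False, False, False, True, True]
        s, _p = stats.position_score_1d(values, flags)
        assert s == pytest.approx(1.0)

    def test_members_on_bottom(self):
        s, _p = stats.position_score_1d([1, 2, 3, 10, 11],
                                        [True, True, False, False, False])
        assert s == pytest.approx(-1.0)

    def test_member_ranks_3_and_5(self):
        # N=5, members at ranks {3, 5}: 5 of 6 concordant pairs -> s = 2/3
        values = [10, 20, 30, 40, 50]
        flags = [False, False, True, False, True]
        s, _p = stats.position_score_1d(values, flags)
        assert s == pytest.approx(2 / 3, rel=1e-12)

    def test_all_or_no_members_rejected(self):
        with pytest.raises(ValueError):
            stats.position_score_1d([1, 2, 3], [True, True, True])
        with pytest.raises(ValueError):
            stats.position_score_1d([1, 2, 3], [False, False, False])

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.integers(5, 60), st.integers(0, 2**31 - 1))
    def test_mean_rank_and_u_formulas_agree(self, n, seed):
        r = np.random.default_rng(seed)
        values = r.normal(size=n)
        n_in = int(r.integers(1, n))
        flags = np.zeros(n, dtype=bool)
        flags[r.choice(n, n_in, replace=False)] = True
        s, _p = stats.position_score_1d(values, flags)
        ranks = sps.rankdata(values)
        U = ranks[flags].sum() - n_in * (n_in + 1) / 2
        s_u = 2 * U / (n_in * (n - n_in)) - 1
        assert s == pytest.approx(s_u, abs=1e-12)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_invariant_under_monotone_transform(self, seed):
        r = np.random.default_rng(seed)
        values = r.normal(size=30)
        flags = np.zeros(30, dtype=bool)
        flags[r.choice(30, 8, replace=False)] = True
        s1, p1 = stats.position_score_1d(values, flags)
        s2, p2 = stats.position_score_1d(np.exp(values), flags)
        assert s1 == pytest.approx(s2, abs=1e-12)
        assert p1 == pytest.approx(p2, abs=1e-12)


class TestRankManova2D:
    def test_top_ranked_in_both_dims(self):
        x = np.arange(20.0)
        y = np.arange(20.0) ** 2 + 1
        flags = np.zeros(20, dtype=bool)
        flags[-5:] = True
        s_x, s_y, p, _ = stats.rank_manova_2d(x, y, flags)
        assert s_x == pytest.approx(1.0) and s_y == pytest.approx(1.0)
        assert p < 0.001

    def test_degenerate_dimension_rejected(self):
        with pytest.raises(ValueError, match="degenerate dimension"):
            stats.rank_manova_2d([1.0] * 10, np.arange(10.0), [True] * 3 + [False] * 7)

    def test_identical_dimensions_take_regularized_path(self, rng):
        x = rng.normal(size=40)
        flags = np.zeros(40, dtype=bool)
        flags[:8] = True
        s_x, s_y, p, reg = stats.rank_manova_2d(x, x, flags)
        assert reg
        assert s_x == pytest.approx(s_y)
        assert 0.0 <= p <= 1.0

    def test_null_p_uniform(self, rng):
        # members drawn from the same distribution: p-values ~ Uniform(0,1)
        ps = []
        flags = np.zeros(400, dtype=bool)
        flags[:40] = True
        for _ in range(300):
            x = rng.normal(size=400)
            y = rng.normal(size=400)
            ps.append(stats.rank_manova_2d(x, y, flags)[2])
        assert sps.kstest(ps, "uniform").pvalue > 0.01


class TestCorrelation:
    def test_monotone_vs_linear(self):
        x = np.arange(1.0, 11.0)
        y = x**2
        rho_s, _ = stats.correlation(x, y, "spearman")
        r_p, _ = stats.correlation(x, y, "pearson")
        assert rho_s == pytest.approx(1.0)
        assert r_p < 1.0

    def test_perfect_negative(self):
        x = np.arange(10.0)
        assert stats.correlation(x, -x, "pearson")[0] == pytest.approx(-1.0)
        assert stats.correlation(x, -x, "spearman")[0] == pytest.approx(-1.0)

    def test_spearman_midranks_hand_example(self):
        x = [1, 2, 2, 3]
        y = [1, 2, 3, 3]
        # mid-ranks: x -> (1, 2.5, 2.5, 4); y -> (1, 2, 3.5, 3.5)
        rx = np.array([1.0, 2.5, 2.5, 4.0])
        ry = np.array([1.0, 2.0, 3.5, 3.5])
        expected = np.corrcoef(rx, ry)[0, 1]
        rho, _ = stats.correlation(x, y, "spearman")
        assert rho == pytest.approx(expected, rel=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            stats.correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
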