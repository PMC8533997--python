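"""Rank tests, exact r x c independence test, correlation, Welch t."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats as sps

from methtopo.errors import ValidationError
from methtopo.stats import (RxCTable, TestResult, bonferroni_report,
                            freeman_halton_exact, kruskal_wallis,
                            mann_whitney_u, spearman, welch_t)


def exact_mwu_p_by_enumeration(x, y):
    """Brute force: two-sided exact p over all rank assignments."""
    pooled = sorted(list(x) + list(y))
    n1, n = len(x), len(x) + len(y)
    us = []
    for combo in itertools.combinations(range(n), n1):
        ranks = [i + 1 for i in combo]
        u = sum(ranks) - n1 * (n1 + 1) / 2
        us.append(u)
    ranks_x = [pooled.index(v) + 1 for v in sorted(x)]
    u_obs = sum(ranks_x) - n1 * (n1 + 1) / 2
    us = np.array(us)
    lo = np.mean(us <= u_obs)
    hi = np.mean(us >= u_obs)
    return min(1.0, 2 * min(lo, hi))


class TestMannWhitney:
    def test_identical_samples_give_p_one(self):
        res = mann_whitney_u([1, 2, 3], [1, 2, 3])
        assert res.p_value == pytest.approx(1.0)

    def test_fully_separated_small_samples(self):
        res = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert res.method == "mann-whitney-exact"
        assert res.p_value == pytest.approx(0.1)  # 2 of C(6,3)=20 orderings

    def test_exact_path_matches_enumeration(self, rng):
        x = rng.normal(size=4)
        y = rng.normal(loc=1.0, size=3)
        res = mann_whitney_u(x, y)
        assert res.method == "mann-whitney-exact"
        assert res.p_value == pytest.approx(exact_mwu_p_by_enumeration(x, y))

    def test_asymptotic_close_to_exact_at_moderate_n(self, rng):
        x = rng.normal(size=10)
        y = rng.normal(loc=0.8, size=10)
        exact = mann_whitney_u(x, y)
        assert exact.method == "mann-whitney-exact"
        approx = sps.mannwhitneyu(x, y, alternative="two-sided",
                                  method="asymptotic").pvalue
        assert abs(exact.p_value - approx) < 0.01

    def test_ties_or_large_samples_use_normal_path(self, rng):
        res = mann_whitney_u([1, 1, 2], [2, 3, 3])
        assert res.method == "mann-whitney-normal"
        res = mann_whitney_u(rng.normal(size=15), rng.normal(size=15))
        assert res.method == "mann-whitney-normal"

    def test_empty_sample_rejected(self):
        with pytest.raises(ValidationError):
            mann_whitney_u([], [1.0])

    def test_attainable_exact_p_values_form_valid_distribution(self):
        # P(P <= p) <= p for every attainable p of the exact null at 3+3
        n1 = n2 = 3
        ps = []
        for combo in itertools.combinations(range(n1 + n2), n1):
            x = [float(i) for i in combo]
            y = [float(i) for i in set(range(n1 + n2)) - set(combo)]
            ps.append(mann_whitney_u(x, y).p_value)
        ps = np.array(ps)
        for p in np.unique(ps):
            assert np.mean(ps <= p) <= p + 1e-12


class TestKruskalWallis:
    def test_identical_values_give_zero_h(self):
        res = kruskal_wallis([[5, 5, 5], [5, 5], [5]])
        assert (res.statistic, res.p_value) == (0.0, 1.0)

    def test_maximal_separation_three_groups_of_three(self):
        res = kruskal_wallis([[1, 2, 3], [4, 5, 6], [7, 8, 9]])
        assert res.statistic == pytest.approx(7.2)
        assert res.p_value == pytest.approx(1 - sps.chi2.cdf(7.2, df=2))

    def test_matches_hand_rank_computation_with_ties(self, rng):
        groups = [rng.integers(0, 6, 8).astype(float) for _ in range(3)]
        pooled = np.concatenate(groups)
        ranks = sps.rankdata(pooled)
        n = len(pooled)
        # definitional H with tie correction, assembled independently
        starts = np.cumsum([0] + [len(g) for g in groups[:-1]])
        h = 12.0 / (n * (n + 1)) * sum(
            len(g) * ranks[s:s + len(g)].mean() ** 2 for g, s in zip(groups, starts)
        ) - 3 * (n + 1)
        _, counts = np.unique(pooled, return_counts=True)
        tie = 1 - np.sum(counts ** 3 - counts) / (n ** 3 - n)
        res = kruskal_wallis(groups)
        assert res.statistic == pytest.approx(h / tie, abs=1e-9)

    def test_fewer_than_two_groups_rejected(self):
        with pytest.raises(ValidationError):
            kruskal_wallis([[1, 2, 3]])


class TestSpearman:
    def test_monotone_gives_plus_one(self):
        res = spearman([1, 2, 3, 4], [10, 20, 40, 80])
        assert res.statistic == pytest.approx(1.0)

    def test_antitone_gives_minus_one(self):
        x = np.arange(5.0)
        assert spearman(x, -x).statistic == pytest.approx(-1.0)

    def test_equals_pearson_of_rank_vectors(self, rng):
        x = rng.normal(size=10)
        y = rng.normal(size=10)
        rho = np.corrcoef(sps.rankdata(x), sps.rankdata(y))[0, 1]
        assert spearman(x, y).statistic == pytest.approx(rho, abs=1e-12)

    def test_constant_input_rejected(self):
        with pytest.raises(ValidationError, match="constant"):
            spearman([1, 1, 1], [1, 2, 3])


class TestWelchT:
    def test_identical_groups_give_zero_t(self):
        res = welch_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == pytest.approx(0.0)

    def test_equal_variance_case_matches_pooled_t(self, rng):
        x = rng.normal(size=12)
        y = x + 0.7  # identical sample variance by construction
        res = welch_t(x, y)
        n = len(x)
        sp2 = (x.var(ddof=1) + y.var(ddof=1)) / 2
        t_pooled = (x.mean() - y.mean()) / math.sqrt(sp2 * 2 / n)
        assert res.statistic == pytest.approx(t_pooled, abs=1e-9)

    def test_degenerate_zero_variance_equal_means(self):
        res = welch_t([2.0, 2.0], [2.0, 2.0])
        assert (res.statistic, res.p_value) == (0.0, 1.0)


def hypergeom_two_sided_p(table):
    """Closed-form oracle for 2x2: sum hypergeometric pmf over tables with
    probability <= observed (relative tolerance 1e-7)."""
    (a, b), (c, d) = table
    n = a + b + c + d
    r1, c1 = a + b, a + c
    rv = sps.hypergeom(n, r1, c1)
    support = np.arange(max(0, r1 + c1 - n), min(r1, c1) + 1)
    pmf = rv.pmf(support)
    p_obs = rv.pmf(a)
    return float(pmf[pmf <= p_obs * (1 + 1e-7)].sum())


class TestFreemanHalton:
    def test_2x2_matches_hypergeometric_closed_form(self, rng):
        for _ in range(50):
            t = rng.integers(0, 12, (2, 2))
            if t.sum(axis=0).min() == 0 or t.sum(axis=1).min() == 0:
                continue
            res = freeman_halton_exact(t)
            assert res.p_value == pytest.approx(hypergeom_two_sided_p(t), abs=1e-10)

    def test_zero_margin_is_degenerate(self):
        with pytest.warns(UserWarning, match="zero margin|degenerate"):
            res = freeman_halton_exact([[3, 0], [5, 0]])
        assert res.p_value == 1.0

    def test_invariant_under_row_permutation_and_transpose(self, rng):
        t = rng.integers(1, 10, (3, 3))
        p = freeman_halton_exact(t).p_value
        assert freeman_halton_exact(t[[2, 0, 1]]).p_value == pytest.approx(p, abs=1e-12)
        assert freeman_halton_exact(t.T).p_value == pytest.approx(p, abs=1e-12)

    def test_enumeration_budget_refused_not_approximated(self):
        big = np.full((5, 5), 40)
        with pytest.raises(ValidationError, match="enumeration refused"):
            freeman_halton_exact(big, budget=10_000)

    def test_non_integer_counts_rejected(self):
        with pytest.raises(ValidationError):
            RxCTable(np.array([[1.5, 2.0], [3.0, 4.0]]))

    def test_type_one_error_conservative_under_null(self, rng):
        # multinomial 3x2 tables with independent margins, n=60
        p_row = np.array([0.4, 0.35, 0.25])
        p_col = np.array([0.6, 0.4])
        cell_p = np.outer(p_row, p_col).ravel()
        reps = 2000
        rejections = 0
        for _ in range(reps):
            t = rng.multinomial(60, cell_p).reshape(3, 2)
            if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
                continue
            if freeman_halton_exact(t).p_value < 0.05:
                rejections += 1
        rate = rejections / reps
        mc_se = math.sqrt(0.05 * 0.95 / reps)
        assert rate <= 0.05 + 2 * mc_se


class TestBonferroni:
    def res(self, p):
        return TestResult(0.0, p, "x", (10,))

    def test_threshold_is_strict(self):
        out = bonferroni_report([self.res(0.0100)], 5)[0]
        assert out.significant is False  # 0.01 is not < 0.05/5

    def test_small_p_significant_at_divisor_15(self):
        assert bonferroni_report([self.res(0.001)], 15)[0].significant

    def test_divisor_one_is_plain_alpha(self):
        assert bonferroni_report([self.res(0.049)], 1)[0].significant
        assert not bonferroni_report([self.res(0.051)], 1)[0].significant

    def test_dict_form_preserved(self):
        out = bonferroni_report({"a": self.res(0.002)}, 11)
        assert out["a"].bonferroni_m == 11 and out["a"].significant
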