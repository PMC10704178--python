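"""Exact 2x2 inference and rank tests against independent oracles.

Oracles: exact-fraction hypergeometric enumeration (Fisher p), brute-force
permutation enumeration (Mann-Whitney), dense grid search of the
noncentral hypergeometric likelihood (conditional MLE), and scipy /
statsmodels reference implementations.
"""

import itertools
import math
from fractions import Fraction
from math import comb

import numpy as np
import pytest
import scipy.stats as ss

from glurare.stats import (
    TwoByTwoTable,
    bonferroni,
    burden_or_logistic,
    conditional_mle_or,
    exact_or_ci,
    fisher_two_sided_p,
    mann_whitney_u,
    noncentral_hypergeom_support,
)

GRIN3A_TABLE = TwoByTwoTable(7, 7, 12, 57)  # behavioral-ADR carriers in the study cohort


# --- independent oracles ---------------------------------------------------


def fisher_p_oracle(t: TwoByTwoTable) -> float:
    """Minimum-likelihood two-sided Fisher p by exact rational enumeration."""
    if t.has_zero_margin():
        return 1.0
    lo, hi = t.support
    weights = {k: comb(t.row1, k) * comb(t.row2, t.col1 - k) for k in range(lo, hi + 1)}
    total = sum(weights.values())
    w_obs = weights[t.a]
    return float(Fraction(sum(w for w in weights.values() if w <= w_obs), total))


def mw_p_oracle(x, y) -> float:
    """Two-sided exact Mann-Whitney p by full enumeration of labelings."""
    pooled = np.asarray(list(x) + list(y), dtype=float)
    n1, n = len(x), len(pooled)
    ranks = ss.rankdata(pooled)
    mu = n1 * (n - n1) / 2

    def u_of(idx):
        return sum(ranks[i] for i in idx) - n1 * (n1 + 1) / 2

    dev_obs = abs(u_of(range(n1)) - mu)
    devs = [abs(u_of(c) - mu) for c in itertools.combinations(range(n), n1)]
    return sum(d >= dev_obs - 1e-9 for d in devs) / len(devs)


def cmle_grid_oracle(t: TwoByTwoTable) -> float:
    """Two-stage dense grid maximizer of the noncentral hypergeometric likelihood."""
    lo, hi = t.support
    coeff = {k: comb(t.row1, k) * comb(t.row2, t.col1 - k) for k in range(lo, hi + 1)}

    def loglik(log_psi):
        logs = [math.log(c) + k * log_psi for k, c in coeff.items()]
        m = max(logs)
        return math.log(coeff[t.a]) + t.a * log_psi - (m + math.log(sum(math.exp(v - m) for v in logs)))

    grid = np.linspace(-8, 8, 801)
    best = grid[int(np.argmax([loglik(g) for g in grid]))]
    fine = np.linspace(best - 0.05, best + 0.05, 2001)
    best = fine[int(np.argmax([loglik(g) for g in fine]))]
    return math.exp(best)


def random_interior_tables(rng, n_tables, max_cell=15):
    """Random 2x2 tables whose first cell is interior to the conditional support."""
    tables = []
    while len(tables) < n_tables:
        a, b, c, d = (int(rng.integers(0, max_cell + 1)) for _ in range(4))
        if a + b + c + d == 0:
            continue
        t = TwoByTwoTable(a, b, c, d)
        lo, hi = t.support
        if lo < t.a < hi:
            tables.append(t)
    return tables


# --- Mann-Whitney ----------------------------------------------------------


class TestMannWhitney:
    def test_exact_small_example(self):
        # one labeling per tail attains the extreme U among C(5,2)=10
        u, p = mann_whitney_u([4, 5], [1, 2, 3], mode="exact")
        assert u == 6.0
        assert p == pytest.approx(0.2, abs=1e-12)

    def test_all_tied_is_uninformative(self):
        _, p = mann_whitney_u([1, 1, 1], [1, 1, 1])
        assert p == 1.0

    def test_exact_with_ties_matches_enumeration(self):
        x, y = [0, 0, 0, 1], [2, 2, 3, 3]
        _, p = mann_whitney_u(x, y, mode="exact")
        assert p == pytest.approx(mw_p_oracle(x, y), abs=1e-12)

    @pytest.mark.parametrize("seed", range(12))
    def test_exact_matches_enumeration_random(self, seed):
        rng = np.random.default_rng(1000 + seed)
        n1 = int(rng.integers(1, 6))
        n2 = int(rng.integers(1, 11 - n1))
        vals = rng.integers(0, 4, size=n1 + n2)  # heavy ties
        x, y = vals[:n1], vals[n1:]
        _, p = mann_whitney_u(x, y, mode="exact")
        assert p == pytest.approx(mw_p_oracle(x, y), abs=1e-12)

    def test_approximate_matches_scipy(self):
        rng = np.random.default_rng(5)
        x = rng.integers(0, 5, size=30)
        y = rng.integers(0, 6, size=40)
        u, p = mann_whitney_u(x, y, mode="approximate")
        ref = ss.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        assert u == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_auto_switches_to_exact_when_feasible(self):
        x, y = [1.5, 2.5], [0.5, 3.5, 4.5]
        assert mann_whitney_u(x, y, mode="auto")[1] == mann_whitney_u(x, y, mode="exact")[1]

    def test_empty_group_rejected(self):
        with pytest.raises(Exception, match="degenerate"):
            mann_whitney_u([], [1, 2])


# --- Fisher exact p --------------------------------------------------------


class TestFisherP:
    @pytest.mark.parametrize(
        "table, expected",
        [
            ((3, 1, 1, 3), 34 / 70),
            ((5, 5, 5, 5), 1.0),
            ((0, 5, 5, 0), 2 / 252),
        ],
    )
    def test_small_enumerable_tables(self, table, expected):
        assert fisher_two_sided_p(TwoByTwoTable(*table)) == pytest.approx(expected, abs=1e-12)

    def test_study_grin3a_table(self):
        assert fisher_two_sided_p(GRIN3A_TABLE) == pytest.approx(0.0143, abs=5e-5)

    def test_zero_margin_convention(self):
        assert fisher_two_sided_p(TwoByTwoTable(0, 0, 3, 4)) == 1.0

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_scipy_random(self, seed):
        rng = np.random.default_rng(200 + seed)
        a, b, c, d = (int(x) for x in rng.integers(0, 20, size=4))
        if a + b + c + d == 0:
            a = 1
        t = TwoByTwoTable(a, b, c, d)
        assert fisher_two_sided_p(t) == pytest.approx(
            ss.fisher_exact([[a, b], [c, d]])[1], rel=1e-9, abs=1e-12
        )


# --- conditional MLE odds ratio -------------------------------------------


class TestConditionalMle:
    def test_symmetric_table_is_unity(self):
        assert conditional_mle_or(TwoByTwoTable(5, 5, 5, 5)) == pytest.approx(1.0, abs=1e-9)

    def test_study_grin3a_table(self):
        assert conditional_mle_or(GRIN3A_TABLE) == pytest.approx(4.64, abs=5e-3)

    def test_boundary_upper_support(self):
        assert conditional_mle_or(TwoByTwoTable(3, 0, 1, 4)) == math.inf

    def test_boundary_lower_support(self):
        assert conditional_mle_or(TwoByTwoTable(0, 3, 4, 1)) == 0.0

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_grid_search(self, seed):
        rng = np.random.default_rng(300 + seed)
        for t in random_interior_tables(rng, 5):
            psi = conditional_mle_or(t)
            ref = cmle_grid_oracle(t)
            assert psi == pytest.approx(ref, rel=2e-3)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_scipy_conditional(self, seed):
        rng = np.random.default_rng(400 + seed)
        for t in random_interior_tables(rng, 5):
            ref = ss.contingency.odds_ratio([[t.a, t.b], [t.c, t.d]], kind="conditional").statistic
            assert conditional_mle_or(t) == pytest.approx(ref, rel=1e-6)

    def test_conditional_mean_monotone_in_psi(self):
        """E[A | margins, psi] strictly increases in psi (uniqueness of the MLE)."""
        rng = np.random.default_rng(17)
        for t in random_interior_tables(rng, 10):
            psis = np.exp(np.linspace(-3, 3, 25))
            means = [float((k * p).sum()) for k, p in (noncentral_hypergeom_support(t, x) for x in psis)]
            assert all(m2 > m1 for m1, m2 in zip(means, means[1:]))

    def test_column_swap_inverts_odds_ratio(self):
        rng = np.random.default_rng(23)
        for t in random_interior_tables(rng, 10):
            assert conditional_mle_or(t.swap_columns()) == pytest.approx(
                1.0 / conditional_mle_or(t), rel=1e-8
            )


# --- exact CI --------------------------------------------------------------


class TestExactCI:
    def test_study_grin3a_interval(self):
        lo, hi = exact_or_ci(GRIN3A_TABLE, 0.95)
        assert lo == pytest.approx(1.16, abs=5e-3)
        assert hi == pytest.approx(18.97, rel=5e-3)

    def test_symmetric_table_reciprocal_endpoints(self):
        lo, hi = exact_or_ci(TwoByTwoTable(5, 5, 5, 5), 0.95)
        assert lo < 1 < hi
        assert lo == pytest.approx(1.0 / hi, rel=1e-8)

    def test_nesting_in_level(self):
        rng = np.random.default_rng(31)
        for t in random_interior_tables(rng, 8):
            lo95, hi95 = exact_or_ci(t, 0.95)
            lo99, hi99 = exact_or_ci(t, 0.99)
            assert lo99 <= lo95 and hi99 >= hi95

    def test_boundary_endpoints(self):
        lo, hi = exact_or_ci(TwoByTwoTable(3, 0, 1, 4), 0.95)
        assert hi == math.inf and lo > 0
        lo, hi = exact_or_ci(TwoByTwoTable(0, 3, 4, 1), 0.95)
        assert lo == 0.0 and hi < math.inf

    def test_endpoints_satisfy_tail_equations(self):
        """Scipy's noncentral hypergeometric tails vanish to alpha/2 at the endpoints."""
        rng = np.random.default_rng(37)
        for t in random_interior_tables(rng, 8):
            lo, hi = exact_or_ci(t, 0.95)
            n, r1, c1 = t.n, t.row1, t.col1
            upper_tail = ss.nchypergeom_fisher.sf(t.a - 1, n, r1, c1, lo)
            lower_tail = ss.nchypergeom_fisher.cdf(t.a, n, r1, c1, hi)
            assert upper_tail == pytest.approx(0.025, abs=1e-8)
            assert lower_tail == pytest.approx(0.025, abs=1e-8)

    def test_swap_symmetry(self):
        rng = np.random.default_rng(41)
        for t in random_interior_tables(rng, 8):
            lo, hi = exact_or_ci(t, 0.95)
            lo_s, hi_s = exact_or_ci(t.swap_columns(), 0.95)
            assert lo_s == pytest.approx(1.0 / hi, rel=1e-6)
            assert hi_s == pytest.approx(1.0 / lo, rel=1e-6)


# --- logistic companion OR -------------------------------------------------


class TestBurdenLogistic:
    def test_constant_counts_gives_unit_or(self):
        r = burden_or_logistic([2, 2, 2, 2], [0, 1, 0, 1])
        assert r.odds_ratio == 1.0 and r.degenerate

    def test_perfect_separation_flagged(self):
        r = burden_or_logistic([0, 0, 1, 1], [0, 0, 1, 1])
        assert r.separated and r.odds_ratio == math.inf

    def test_matches_statsmodels(self):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(53)
        x = rng.poisson(1.2, 300).astype(float)
        eta = -1.0 + 0.6 * x
        y = (rng.random(300) < 1 / (1 + np.exp(-eta))).astype(int)
        r = burden_or_logistic(x, y)
        fit = sm.Logit(y, sm.add_constant(x)).fit(disp=0)
        assert r.odds_ratio == pytest.approx(math.exp(fit.params[1]), rel=1e-6)
        lo, hi = np.exp(fit.conf_int()[1])
        assert r.ci_low == pytest.approx(lo, rel=1e-6)
        assert r.ci_high == pytest.approx(hi, rel=1e-6)

    def test_wald_ci_calibration(self):
        """At a known generative slope the Wald CI covers near nominally."""
        rng = np.random.default_rng(59)
        n, true_or, hits, reps = 5000, 2.0, 0, 60
        for _ in range(reps):
            x = rng.poisson(0.8, n).astype(float)
            eta = -2.0 + math.log(true_or) * x
            y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
            r = burden_or_logistic(x, y)
            hits += r.ci_low <= true_or <= r.ci_high
        assert 0.85 <= hits / reps <= 1.0


def test_bonferroni_thresholds():
    assert bonferroni(0.05, 26) == pytest.approx(1.92e-3, rel=2e-3)
    assert bonferroni(0.05, 5) == 0.01
    assert bonferroni(0.05, 1) == 0.05
    with pytest.raises(Exception):
        bonferroni(0.05, 0)
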