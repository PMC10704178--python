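"""Exact small-sample association statistics for 2x2 tables and rank tests.

This module implements the inferential core from first principles:

* the two-sided Fisher exact test under the minimum-likelihood summation
  rule (the convention of R's ``fisher.test`` and most software);
* the conditional maximum-likelihood odds ratio of a 2x2 table, i.e. the
  value of the noncentral (Fisher) hypergeometric noncentrality that makes
  the expected first cell equal the observed one;
* the central exact confidence interval obtained by inverting the
  noncentral hypergeometric tail probabilities;
* the Mann-Whitney U test with midrank tie handling, both by exact
  permutation enumeration (dynamic programming over the pooled multiset)
  and by the tie-corrected normal approximation with continuity
  correction;
* a companion logistic odds ratio per unit burden count (Newton-Raphson,
  Wald CI), reported descriptively alongside the rank test;
* the Bonferroni family-wise threshold.

All routines are deterministic pure functions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.special import gammaln, ndtr

from .types import GlurareError

__all__ = [
    "TwoByTwoTable",
    "bonferroni",
    "burden_or_logistic",
    "conditional_mle_or",
    "exact_or_ci",
    "fisher_two_sided_p",
    "mann_whitney_u",
    "noncentral_hypergeom_support",
]

#: Relative tolerance when comparing table probabilities for the
#: minimum-likelihood two-sided rule (guards against float round-off when
#: two tables are equally likely).
_P_REL_EPS = 1e-7


@dataclass(frozen=True)
class TwoByTwoTable:
    """2x2 contingency table with the orientation contract
    rows = outcome present/absent, columns = exposure (carrier) yes/no:

    ========== ========= ============
               carrier    non-carrier
    ========== ========= ============
    outcome      a          b
    no outcome   c          d
    ========== ========= ============
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        cells = (self.a, self.b, self.c, self.d)
        if any(int(x) != x or x < 0 for x in cells):
            raise GlurareError(f"table cells must be non-negative integers, got {cells}")
        if sum(cells) == 0:
            raise GlurareError("empty 2x2 table")

    @property
    def row1(self) -> int:
        return self.a + self.b

    @property
    def row2(self) -> int:
        return self.c + self.d

    @property
    def col1(self) -> int:
        return self.a + self.c

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def support(self) -> tuple[int, int]:
        """Range (inclusive) of the first cell given all margins."""
        lo = max(0, self.col1 - self.row2)
        hi = min(self.row1, self.col1)
        return lo, hi

    def swap_columns(self) -> "TwoByTwoTable":
        return TwoByTwoTable(self.b, self.a, self.d, self.c)

    def has_zero_margin(self) -> bool:
        return 0 in (self.row1, self.row2, self.col1, self.n - self.col1)


def noncentral_hypergeom_support(
    t: TwoByTwoTable, psi: float = 1.0
) -> tuple[np.ndarray, np.ndarray]:
    """Support and probabilities of the first cell under noncentrality ``psi``.

    The first cell A of a 2x2 table with all margins fixed follows the
    noncentral hypergeometric law: P(A = k) proportional to
    ``C(r1, k) C(r2, c1 - k) psi**k``.  Returns ``(support, probs)``;
    computed in log space for stability.
    """
    lo, hi = t.support
    k = np.arange(lo, hi + 1)
    logw = (
        _log_comb(t.row1, k)
        + _log_comb(t.row2, t.col1 - k)
        + k * (math.log(psi) if psi > 0 else -math.inf)
    )
    if psi == 0:
        # point mass at the lower support bound
        probs = np.zeros_like(k, dtype=float)
        probs[0] = 1.0
        return k, probs
    logw -= logw.max()
    w = np.exp(logw)
    return k, w / w.sum()


def _log_comb(n: int, k: np.ndarray) -> np.ndarray:
    k = np.asarray(k)
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def fisher_two_sided_p(t: TwoByTwoTable) -> float:
    """Two-sided Fisher exact p-value (minimum-likelihood rule).

    Sums the central hypergeometric probabilities of every table sharing
    the observed margins whose probability does not exceed that of the
    observed table (within a small relative tolerance).  A table with a
    zero margin carries no information and returns 1.
    """
    if t.has_zero_margin():
        return 1.0
    k, probs = noncentral_hypergeom_support(t, 1.0)
    p_obs = probs[int(t.a - k[0])]
    p = float(probs[probs <= p_obs * (1.0 + _P_REL_EPS)].sum())
    return min(p, 1.0)


def _conditional_mean(t: TwoByTwoTable, log_psi: float) -> float:
    lo, hi = t.support
    k = np.arange(lo, hi + 1)
    logw = _log_comb(t.row1, k) + _log_comb(t.row2, t.col1 - k) + k * log_psi
    logw -= logw.max()
    w = np.exp(logw)
    return float((k * w).sum() / w.sum())


def _tail_prob(t: TwoByTwoTable, log_psi: float, upper: bool) -> float:
    """P(A >= a | psi) if ``upper`` else P(A <= a | psi)."""
    lo, hi = t.support
    k = np.arange(lo, hi + 1)
    logw = _log_comb(t.row1, k) + _log_comb(t.row2, t.col1 - k) + k * log_psi
    logw -= logw.max()
    w = np.exp(logw)
    mask = k >= t.a if upper else k <= t.a
    return float(w[mask].sum() / w.sum())


def _solve_log_psi(f, target: float, increasing: bool) -> float:
    """Solve f(log psi) = target for a function monotone in log psi."""

    def g(x: float) -> float:
        return f(x) - target

    lo, hi = -1.0, 1.0
    for _ in range(200):
        glo, ghi = g(lo), g(hi)
        want_lo_neg = increasing
        if (glo < 0) == want_lo_neg and (ghi > 0) == want_lo_neg:
            break
        if (glo < 0) != want_lo_neg:
            lo *= 2.0
        if (ghi > 0) != want_lo_neg:
            hi *= 2.0
        if hi > 1500:  # beyond any representable odds ratio
            raise GlurareError("root bracketing failed for odds-ratio solve")
    return brentq(g, lo, hi, xtol=1e-12, rtol=8.9e-16, maxiter=200)


def conditional_mle_or(t: TwoByTwoTable) -> float:
    """Conditional maximum-likelihood odds ratio of a 2x2 table.

    Solves ``E[A | margins, psi] = a`` where A is noncentral
    hypergeometric; the conditional mean is strictly increasing in psi on
    the interior of the support, so the root is unique.  Returns 0 when
    the observed cell sits at the lower support bound and ``inf`` at the
    upper bound (the likelihood is then maximized in the limit).
    """
    lo, hi = t.support
    if lo == hi:  # degenerate margin: single possible table
        return 1.0
    if t.a == lo:
        return 0.0
    if t.a == hi:
        return math.inf
    log_psi = _solve_log_psi(lambda x: _conditional_mean(t, x), float(t.a), increasing=True)
    return math.exp(log_psi)


def exact_or_ci(t: TwoByTwoTable, level: float = 0.95) -> tuple[float, float]:
    """Central exact (conditional) confidence interval for the odds ratio.

    The lower endpoint solves ``P(A >= a | psi) = (1 - level) / 2`` and
    the upper endpoint solves ``P(A <= a | psi) = (1 - level) / 2``; both
    tails are noncentral hypergeometric.  Endpoints at the support
    boundaries are 0 and ``inf`` respectively.
    """
    if not (0.0 < level < 1.0):
        raise GlurareError(f"confidence level {level} out of (0, 1)")
    lo_s, hi_s = t.support
    alpha2 = (1.0 - level) / 2.0
    if lo_s == hi_s:
        return 0.0, math.inf
    if t.a == lo_s:
        lo = 0.0
    else:
        # P(A >= a | psi) increases with psi
        lo = math.exp(_solve_log_psi(lambda x: _tail_prob(t, x, upper=True), alpha2, increasing=True))
    if t.a == hi_s:
        hi = math.inf
    else:
        # P(A <= a | psi) decreases with psi
        hi = math.exp(_solve_log_psi(lambda x: _tail_prob(t, x, upper=False), alpha2, increasing=False))
    return lo, hi


# ---------------------------------------------------------------------------
# Mann-Whitney U
# ---------------------------------------------------------------------------

#: Pooled-sample-size cap below which ``mode='auto'`` uses the exact
#: permutation distribution (when the pooled values are tie-free).
EXACT_N_MAX = 25


def _midranks(pooled: np.ndarray) -> np.ndarray:
    order = np.argsort(pooled, kind="stable")
    ranks = np.empty(len(pooled), dtype=float)
    sorted_vals = pooled[order]
    i = 0
    while i < len(pooled):
        j = i
        while j + 1 < len(pooled) and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


def _exact_two_sided_p(doubled_ranks: np.ndarray, n1: int, two_u_obs: int) -> float:
    """Exact P(|2U - n1*n2| >= |2u - n1*n2|) by DP over the pooled multiset.

    Works on doubled midranks so every rank sum is an integer.  The
    permutation distribution of U is symmetric about n1*n2/2 (reversing
    the value order maps U to n1*n2 - U), so the two-sided p-value is the
    symmetric tail mass.
    """
    n = len(doubled_ranks)
    n2 = n - n1
    max_sum = int(doubled_ranks.sum())
    # dp[c, s] = number of size-c subsets of the processed items with
    # doubled-rank sum s
    dp = np.zeros((n1 + 1, max_sum + 1), dtype=np.float64)
    dp[0, 0] = 1.0
    for v in doubled_ranks.astype(int):
        dp[1:, v:] += dp[:-1, : max_sum + 1 - v]
    counts = dp[n1]
    total = counts.sum()
    sums = np.arange(max_sum + 1)
    two_u = sums - n1 * (n1 + 1)  # 2*U for each possible rank sum
    dev_obs = abs(two_u_obs - n1 * n2)
    tail = counts[np.abs(two_u - n1 * n2) >= dev_obs].sum()
    return float(min(tail / total, 1.0))


def mann_whitney_u(
    x: Sequence[float],
    y: Sequence[float],
    mode: str = "auto",
) -> tuple[float, float]:
    """Mann-Whitney U test of ``x`` (outcome-present group) vs ``y``.

    Returns ``(U, p)`` where U counts pairs ``(xi, yj)`` with ``xi > yj``
    plus half the ties (midrank convention) and ``p`` is two-sided.

    ``mode='exact'`` enumerates the permutation distribution of U given
    the pooled multiset via dynamic programming (ties handled exactly);
    ``mode='approximate'`` uses the normal approximation with
    tie-corrected variance and a 0.5 continuity correction;
    ``mode='auto'`` picks exact for tie-free pooled samples of at most
    25 observations and the approximation otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise GlurareError("degenerate grouping: both groups must be non-empty")
    if mode not in ("auto", "exact", "approximate"):
        raise GlurareError(f"unknown mode {mode!r}")
    n1, n2 = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = _midranks(pooled)
    r1 = float(ranks[:n1].sum())
    u = r1 - n1 * (n1 + 1) / 2.0

    has_ties = len(np.unique(pooled)) < len(pooled)
    if mode == "auto":
        mode = "exact" if (not has_ties and n1 + n2 <= EXACT_N_MAX) else "approximate"

    if mode == "exact":
        doubled = np.rint(2.0 * ranks).astype(int)
        two_u_obs = int(round(2.0 * u))
        p = _exact_two_sided_p(doubled.astype(float), n1, two_u_obs)
        return u, p

    mu = n1 * n2 / 2.0
    n = n1 + n2
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float((tie_counts**3 - tie_counts).sum())
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:  # every observation tied: no information
        return u, 1.0
    dev = u - mu
    cc = 0.5 if dev != 0 else 0.0
    z = (abs(dev) - cc) / math.sqrt(var)
    z = max(z, 0.0)
    p = 2.0 * (1.0 - float(ndtr(z)))
    return u, min(p, 1.0)


# ---------------------------------------------------------------------------
# Companion logistic odds ratio for burden counts
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LogisticOR:
    """Descriptive per-unit-count odds ratio from a two-parameter logistic fit.

    ``separated`` flags perfect separation (infinite MLE, no Wald CI);
    ``degenerate`` flags constant counts (slope pinned to 0, OR = 1).
    """

    odds_ratio: float
    ci_low: float
    ci_high: float
    separated: bool = False
    degenerate: bool = False


def burden_or_logistic(
    counts: Sequence[float], outcome: Sequence[int], level: float = 0.95
) -> LogisticOR:
    """Per-unit-count odds ratio from ``logit P(outcome) = b0 + b1 * count``.

    Fit by Newton-Raphson on the two-parameter logistic likelihood; the
    Wald CI uses the observed information at the MLE.  Reported as a
    descriptive companion to the Mann-Whitney burden test — significance
    decisions never rest on it.
    """
    counts = np.asarray(counts, dtype=float)
    y = np.asarray(outcome, dtype=float)
    if counts.shape != y.shape:
        raise GlurareError("counts and outcome must have equal length")
    if not (set(np.unique(y)) <= {0.0, 1.0}) or len(np.unique(y)) < 2:
        raise GlurareError("outcome must be binary with both classes present")
    if np.ptp(counts) == 0:
        return LogisticOR(1.0, math.nan, math.nan, degenerate=True)
    # complete or quasi-complete separation on a single covariate
    if counts[y == 1].min() >= counts[y == 0].max():
        return LogisticOR(math.inf, math.nan, math.nan, separated=True)
    if counts[y == 1].max() <= counts[y == 0].min():
        return LogisticOR(0.0, math.nan, math.nan, separated=True)

    X = np.column_stack([np.ones_like(counts), counts])
    beta = np.zeros(2)
    for _ in range(100):
        eta = X @ beta
        p = 1.0 / (1.0 + np.exp(-eta))
        w = p * (1.0 - p)
        grad = X.T @ (y - p)
        hess = X.T @ (X * w[:, None])
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            return LogisticOR(math.inf, math.nan, math.nan, separated=True)
        beta = beta + step
        if np.abs(step).max() < 1e-10:
            break
        if abs(beta[1]) > 30:  # drifting to infinity: numerical separation
            return LogisticOR(math.inf if beta[1] > 0 else 0.0, math.nan, math.nan, separated=True)
    eta = X @ beta
    p = 1.0 / (1.0 + np.exp(-eta))
    w = p * (1.0 - p)
    hess = X.T @ (X * w[:, None])
    cov = np.linalg.inv(hess)
    se = math.sqrt(cov[1, 1])
    zcrit = _norm_ppf(0.5 + level / 2.0)
    return LogisticOR(
        odds_ratio=math.exp(beta[1]),
        ci_low=math.exp(beta[1] - zcrit * se),
        ci_high=math.exp(beta[1] + zcrit * se),
    )


def _norm_ppf(q: float) -> float:
    from scipy.special import ndtri

    return float(ndtri(q))


def bonferroni(alpha: float, m: int) -> float:
    """Family-wise threshold ``alpha / m`` for a family of ``m`` tests."""
    if m < 1:
        raise GlurareError(f"family size must be >= 1, got {m}")
    return alpha / m
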