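"""Nonparametric statistical battery with exact small-sample nulls.

Every test is implemented from first principles so the exact null
distributions are auditable:

* Mann-Whitney U -- exact p by rank-sum counting (dynamic programming)
  for ``n1 + n2 <= 25`` tie-free samples, otherwise a normal
  approximation with tie correction and 0.5 continuity correction.
* Wilcoxon signed rank -- exact p by signed rank-sum counting for
  ``n <= 20`` with untied |differences|; zero differences are dropped
  (Wilcoxon's original proposal; Pratt's variant would change p).
* Friedman -- chi-square statistic on within-block average ranks;
  exact p by full within-block permutation enumeration for small
  layouts, chi-square (k-1 df) otherwise.
* Holm step-down adjustment.
* Spearman -- Pearson correlation of average ranks; exact permutation
  p for ``n <= 8``, t approximation otherwise.
* Lilliefors -- KS distance to a normal with estimated moments; p by
  seeded Monte-Carlo resampling of the null (reproducible at any n,
  unlike table lookup).
* Levene -- classic mean-centered variant (ANOVA F on absolute
  deviations from group means).

All p-values are two-sided unless inherently one-sided (Friedman,
Lilliefors, Levene).
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import stats as _st

from .core import BehaviorSchedule

__all__ = [
    "TestResult",
    "CorrelationResult",
    "mann_whitney_u",
    "wilcoxon_signed_rank",
    "friedman",
    "holm_adjust",
    "spearman",
    "lilliefors",
    "levene",
    "behavior_duration",
]


@dataclass
class TestResult:
    """Outcome of one hypothesis test, with method provenance."""

    __test__ = False  # not a pytest collection target

    name: str
    statistic: float
    p: float
    n: tuple[int, ...]
    method: str  # "exact" | "normal-approx" | "chi2-approx" | "monte-carlo" | "f-dist" | "degenerate"
    ties: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.p <= 1.0:
            raise ValueError(f"p-value {self.p} outside [0, 1]")


@dataclass
class CorrelationResult:
    """Spearman correlation outcome."""

    rho: float
    p: float
    n: int
    level: str = ""  # aggregation-level descriptor
    method: str = "t-approx"

    def __post_init__(self) -> None:
        if not -1.0 - 1e-12 <= self.rho <= 1.0 + 1e-12:
            raise ValueError(f"rho {self.rho} outside [-1, 1]")


# ---------------------------------------------------------------------------
# Rank helpers and exact-null counting
# ---------------------------------------------------------------------------


def _rankdata(a: np.ndarray) -> np.ndarray:
    return _st.rankdata(a, method="average")


@lru_cache(maxsize=128)
def _ranksum_counts(n1: int, n: int) -> tuple[int, ...]:
    """counts[s] = number of size-``n1`` subsets of ranks ``1..n`` with sum
    ``s`` (index offset by the minimum sum)."""
    max_sum = n1 * n
    # dp[k][s]: ways to pick k ranks summing to s.
    dp = np.zeros((n1 + 1, max_sum + 1), dtype=object)
    dp[0][0] = 1
    for r in range(1, n + 1):
        for k in range(min(r, n1), 0, -1):
            dp[k][r:] = dp[k][r:] + dp[k - 1][: max_sum + 1 - r]
    return tuple(int(v) for v in dp[n1])


@lru_cache(maxsize=128)
def _signed_rank_counts(n: int) -> tuple[int, ...]:
    """counts[s] = number of subsets of ranks ``1..n`` with sum ``s``."""
    max_sum = n * (n + 1) // 2
    dp = [0] * (max_sum + 1)
    dp[0] = 1
    for r in range(1, n + 1):
        for s in range(max_sum, r - 1, -1):
            dp[s] += dp[s - r]
    return tuple(dp)


def _two_sided_from_symmetric(cdf_le: float, sf_ge: float) -> float:
    return min(1.0, 2.0 * min(cdf_le, sf_ge))


# ---------------------------------------------------------------------------
# Mann-Whitney U
# ---------------------------------------------------------------------------


def mann_whitney_u(
    x: np.ndarray, y: np.ndarray, exact_limit: int = 25
) -> TestResult:
    """Two-sided Mann-Whitney U test; ``statistic`` is the U of ``x``.

    Exact p by rank-sum enumeration when ``len(x) + len(y) <= exact_limit``
    and the pooled sample is tie-free; otherwise a normal approximation
    with tie correction and 0.5 continuity correction.  The exact-path
    threshold is chosen so a 12 + 12 design is exact when tie-free.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = _rankdata(pooled)
    r1 = float(ranks[:n1].sum())
    u1 = r1 - n1 * (n1 + 1) / 2.0
    ties = np.unique(pooled).size < pooled.size

    if not ties and n1 + n2 <= exact_limit:
        counts = _ranksum_counts(n1, n1 + n2)
        total = math.comb(n1 + n2, n1)
        # counts is indexed by absolute rank sum 0..n1*n; sums below the
        # minimum achievable rank sum have count 0.
        s = int(round(r1))
        cdf_le = sum(counts[: s + 1]) / total
        sf_ge = sum(counts[s:]) / total
        p = _two_sided_from_symmetric(cdf_le, sf_ge)
        return TestResult("mann-whitney-u", float(u1), p, (n1, n2), "exact", ties)

    mu = n1 * n2 / 2.0
    n = n1 + n2
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum())) / (n * (n - 1)) if n > 1 else 0.0
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return TestResult("mann-whitney-u", float(u1), 1.0, (n1, n2), "degenerate", ties)
    z = (abs(u1 - mu) - 0.5) / math.sqrt(var)
    z = max(z, 0.0)
    p = float(min(1.0, 2.0 * _st.norm.sf(z)))
    return TestResult("mann-whitney-u", float(u1), p, (n1, n2), "normal-approx", ties)


# ---------------------------------------------------------------------------
# Wilcoxon signed rank
# ---------------------------------------------------------------------------


def wilcoxon_signed_rank(
    x: np.ndarray, y: np.ndarray, exact_limit: int = 20
) -> TestResult:
    """Two-sided Wilcoxon signed-rank test on paired samples.

    Zero differences are dropped.  ``statistic`` is ``min(W+, W-)``.
    Exact p by sign-pattern enumeration when the number of non-zero
    differences is ``<= exact_limit`` and the |differences| are untied;
    otherwise normal approximation with tie correction and continuity
    correction.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size != y.size:
        raise ValueError("paired samples must have equal length")
    d = x - y
    d = d[d != 0]
    n = d.size
    if n == 0:
        warnings.warn("all differences are zero; p = 1", UserWarning, stacklevel=2)
        return TestResult("wilcoxon-signed-rank", 0.0, 1.0, (0,), "degenerate", False)

    abs_ranks = _rankdata(np.abs(d))
    w_plus = float(abs_ranks[d > 0].sum())
    w_minus = float(abs_ranks[d < 0].sum())
    w = min(w_plus, w_minus)
    ties = np.unique(np.abs(d)).size < n

    if not ties and n <= exact_limit:
        counts = _signed_rank_counts(n)
        total = 2**n
        s = int(round(w))
        cdf_le = sum(counts[: s + 1]) / total
        p = min(1.0, 2.0 * cdf_le)
        return TestResult("wilcoxon-signed-rank", w, p, (n,), "exact", ties)

    mu = n * (n + 1) / 4.0
    _, tie_counts = np.unique(np.abs(d), return_counts=True)
    var = n * (n + 1) * (2 * n + 1) / 24.0 - float((tie_counts**3 - tie_counts).sum()) / 48.0
    if var <= 0:
        return TestResult("wilcoxon-signed-rank", w, 1.0, (n,), "degenerate", ties)
    z = (abs(w_plus - mu) - 0.5) / math.sqrt(var)
    z = max(z, 0.0)
    p = float(min(1.0, 2.0 * _st.norm.sf(z)))
    return TestResult("wilcoxon-signed-rank", w, p, (n,), "normal-approx", ties)


# ---------------------------------------------------------------------------
# Friedman
# ---------------------------------------------------------------------------


def _friedman_chi2(ranks: np.ndarray) -> float:
    n, k = ranks.shape
    col_sums = ranks.sum(axis=0)
    return float(12.0 / (n * k * (k + 1)) * (col_sums**2).sum() - 3.0 * n * (k + 1))


def friedman(block_matrix: np.ndarray, method: str = "auto") -> TestResult:
    """Friedman test on a complete ``blocks x treatments`` matrix.

    The statistic is the classic chi-square-distributed form computed on
    within-block average ranks.  ``method``:

    * ``"auto"`` -- exact permutation when ``n * k <= 16`` and the
      enumeration is tractable, chi-square otherwise;
    * ``"exact"`` -- force full within-block permutation enumeration;
    * ``"chi2"`` -- force the chi-square (k-1 df) approximation.
    """
    m = np.asarray(block_matrix, dtype=np.float64)
    if m.ndim != 2:
        raise ValueError("block matrix must be 2-D (blocks x treatments)")
    if np.isnan(m).any():
        raise ValueError("incomplete block matrix; caller must exclude incomplete blocks")
    n, k = m.shape
    if n < 2 or k < 2:
        raise ValueError(f"need >= 2 blocks and >= 2 treatments, got {m.shape}")

    ranks = np.vstack([_rankdata(row) for row in m])
    chi = _friedman_chi2(ranks)
    ties = any(np.unique(row).size < k for row in m)

    n_perm = math.factorial(k) ** n
    use_exact = method == "exact" or (method == "auto" and n * k <= 16 and n_perm <= 500_000)
    if use_exact:
        if n_perm > 5_000_000:
            raise ValueError(f"exact Friedman enumeration infeasible: {n_perm} permutations")
        perms = list(itertools.permutations(range(k)))
        count = 0
        for combo in itertools.product(perms, repeat=n):
            permuted = np.vstack([ranks[i, list(p)] for i, p in enumerate(combo)])
            if _friedman_chi2(permuted) >= chi - 1e-12:
                count += 1
        p = count / n_perm
        return TestResult("friedman", chi, p, (n, k), "exact", ties)

    p = float(_st.chi2.sf(chi, k - 1))
    return TestResult("friedman", chi, p, (n, k), "chi2-approx", ties)


# ---------------------------------------------------------------------------
# Holm adjustment
# ---------------------------------------------------------------------------


def holm_adjust(pvalues) -> np.ndarray:
    """Holm step-down multiple-comparison adjustment, returned in input
    order: sort ascending, multiply the i-th smallest by ``m - i + 1``,
    enforce the running maximum, cap at 1."""
    p = np.asarray(pvalues, dtype=np.float64)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(m)
    running = 0.0
    for i, idx in enumerate(order):
        running = max(running, (m - i) * p[idx])
        adjusted[idx] = min(1.0, running)
    return adjusted


# ---------------------------------------------------------------------------
# Spearman correlation
# ---------------------------------------------------------------------------


def spearman(x: np.ndarray, y: np.ndarray, level: str = "", exact_limit: int = 8) -> CorrelationResult:
    """Spearman rank correlation: Pearson correlation of average ranks.

    Exact permutation p for ``n <= exact_limit``; t approximation with
    ``n - 2`` df otherwise.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size != y.size:
        raise ValueError("samples must have equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 pairs")
    rx, ry = _rankdata(x), _rankdata(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        raise ValueError("undefined correlation: zero variance in ranks")
    rho = float(np.corrcoef(rx, ry)[0, 1])

    if n <= exact_limit:
        perms = np.array(list(itertools.permutations(range(n))))
        ry_perm = ry[perms]  # (n!, n)
        rx_c = rx - rx.mean()
        ry_c = ry_perm - ry_perm.mean(axis=1, keepdims=True)
        denom = math.sqrt((rx_c**2).sum()) * np.sqrt((ry_c**2).sum(axis=1))
        rhos = (ry_c @ rx_c) / denom
        p = float(np.mean(np.abs(rhos) >= abs(rho) - 1e-12))
        return CorrelationResult(rho, p, n, level, "exact")

    if abs(rho) >= 1.0:
        return CorrelationResult(float(np.sign(rho)), 0.0, n, level, "t-approx")
    t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
    p = float(min(1.0, 2.0 * _st.t.sf(abs(t), n - 2)))
    return CorrelationResult(rho, p, n, level, "t-approx")


# ---------------------------------------------------------------------------
# Distributional diagnostics
# ---------------------------------------------------------------------------


def _ks_distance_to_fitted_normal(x: np.ndarray) -> float:
    n = x.size
    mu = x.mean()
    sd = x.std(ddof=1)
    z = np.sort((x - mu) / sd)
    cdf = _st.norm.cdf(z)
    i = np.arange(1, n + 1)
    return float(max((i / n - cdf).max(), (cdf - (i - 1) / n).max()))


@lru_cache(maxsize=32)
def _lilliefors_null(n: int, n_mc: int, seed: int) -> np.ndarray:
    """Monte-Carlo null distribution of the Lilliefors KS distance for
    sample size ``n`` (vectorized over simulations)."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, n, n_mc]))
    sims = rng.standard_normal((n_mc, n))
    mu = sims.mean(axis=1, keepdims=True)
    sd = sims.std(axis=1, ddof=1, keepdims=True)
    z = np.sort((sims - mu) / sd, axis=1)
    cdf = _st.norm.cdf(z)
    i = np.arange(1, n + 1)
    d_plus = (i / n - cdf).max(axis=1)
    d_minus = (cdf - (i - 1) / n).max(axis=1)
    return np.maximum(d_plus, d_minus)


def lilliefors(x: np.ndarray, n_mc: int = 10_000, seed: int = 0) -> TestResult:
    """Lilliefors normality test (KS distance to a normal with estimated
    mean and SD); p by seeded Monte-Carlo resampling of the null.

    The null distribution is cached per sample size, so repeated calls at
    the same n cost one simulation."""
    x = np.asarray(x, dtype=np.float64)
    n = x.size
    if n < 4:
        raise ValueError("need at least 4 observations")
    if x.std(ddof=1) == 0:
        raise ValueError("degenerate input: zero variance")
    d = _ks_distance_to_fitted_normal(x)
    null = _lilliefors_null(n, n_mc, seed)
    p = float((1 + (null >= d - 1e-15).sum()) / (n_mc + 1))
    return TestResult("lilliefors", d, p, (n,), "monte-carlo", False)


def levene(groups) -> TestResult:
    """Classic mean-centered Levene test: one-way ANOVA F on absolute
    deviations from group means."""
    arrays = [np.asarray(g, dtype=np.float64) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need at least 2 groups")
    if any(a.size < 2 for a in arrays):
        raise ValueError("every group needs at least 2 observations")
    z = [np.abs(a - a.mean()) for a in arrays]
    k = len(z)
    n_total = sum(a.size for a in z)
    grand = sum(a.sum() for a in z) / n_total
    ss_between = sum(a.size * (a.mean() - grand) ** 2 for a in z)
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in z)
    if ss_within <= 0:
        if ss_between <= 0:
            raise ValueError("degenerate input: no variation in absolute deviations")
        return TestResult("levene", math.inf, 0.0, tuple(a.size for a in arrays), "f-dist", False)
    f_stat = (ss_between / (k - 1)) / (ss_within / (n_total - k))
    p = float(_st.f.sf(f_stat, k - 1, n_total - k))
    return TestResult("levene", f_stat, p, tuple(a.size for a in arrays), "f-dist", False)


# ---------------------------------------------------------------------------
# Behavior durations
# ---------------------------------------------------------------------------


def behavior_duration(episodes: BehaviorSchedule, behavior: str) -> tuple[float, int]:
    """Total time (s) spent in ``behavior`` -- the sum of episode
    intervals -- together with the episode count."""
    eps = episodes.for_behavior(behavior)
    return float(sum(e.duration for e in eps)), len(eps)
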