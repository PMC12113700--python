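"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own code paths: enumeration and
direct-definition implementations only, tractable at small n.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy.stats import rankdata


def brute_mann_whitney(x, y) -> tuple[float, float]:
    """Exact two-sided Mann-Whitney by enumerating all label assignments.

    Returns (U of x, p) with p = P(|U - mu| >= |U_obs - mu|) over all
    C(n1+n2, n1) assignments of the pooled values to the first sample.
    """
    x, y = list(x), list(y)
    pooled = x + y
    n1 = len(x)

    def u_stat(first_idx):
        first = [pooled[i] for i in first_idx]
        rest = [pooled[i] for i in range(len(pooled)) if i not in set(first_idx)]
        return sum((a > b) + 0.5 * (a == b) for a in first for b in rest)

    u_obs = sum((a > b) + 0.5 * (a == b) for a in x for b in y)
    mu = n1 * len(y) / 2.0
    count = total = 0
    for comb in itertools.combinations(range(len(pooled)), n1):
        total += 1
        if abs(u_stat(comb) - mu) >= abs(u_obs - mu) - 1e-12:
            count += 1
    return u_obs, count / total


def brute_wilcoxon(x, y) -> tuple[float, float]:
    """Exact two-sided signed-rank test by enumerating all sign patterns."""
    d = np.asarray(x, float) - np.asarray(y, float)
    d = d[d != 0]
    n = d.size
    ranks = rankdata(np.abs(d))
    w_plus = ranks[d > 0].sum()
    w_minus = ranks[d < 0].sum()
    w_obs = min(w_plus, w_minus)
    count = 0
    for signs in itertools.product([0, 1], repeat=n):
        wp = sum(r for r, s in zip(ranks, signs) if s)
        wm = ranks.sum() - wp
        if min(wp, wm) <= w_obs + 1e-12:
            count += 1
    return w_obs, count / 2**n


def _friedman_stat(ranks: np.ndarray) -> float:
    n, k = ranks.shape
    r = ranks.sum(axis=0)
    return 12.0 / (n * k * (k + 1)) * (r**2).sum() - 3.0 * n * (k + 1)


def brute_friedman(m) -> tuple[float, float]:
    """Exact Friedman p by enumerating all within-block permutations."""
    m = np.asarray(m, float)
    n, k = m.shape
    ranks = np.vstack([rankdata(row) for row in m])
    obs = _friedman_stat(ranks)
    perms = list(itertools.permutations(range(k)))
    count = total = 0
    for combo in itertools.product(perms, repeat=n):
        total += 1
        permuted = np.vstack([ranks[i, list(p)] for i, p in enumerate(combo)])
        if _friedman_stat(permuted) >= obs - 1e-12:
            count += 1
    return obs, count / total


def brute_spearman(x, y) -> tuple[float, float]:
    """Exact permutation Spearman: rank-then-Pearson rho, p by enumerating
    all n! pairings."""
    rx = rankdata(x)
    ry = rankdata(y)
    rho_obs = np.corrcoef(rx, ry)[0, 1]
    count = total = 0
    for perm in itertools.permutations(range(len(ry))):
        total += 1
        if abs(np.corrcoef(rx, ry[list(perm)])[0, 1]) >= abs(rho_obs) - 1e-12:
            count += 1
    return float(rho_obs), count / total


def dft_psd(x, fs) -> tuple[np.ndarray, np.ndarray]:
    """One-sided density-scaled periodogram via an explicit DFT sum."""
    x = np.asarray(x, float)
    x = x - x.mean()
    n = x.size
    k = np.arange(n // 2 + 1)
    w = np.exp(-2j * np.pi * np.outer(k, np.arange(n)) / n)
    coeffs = w @ x
    psd = np.abs(coeffs) ** 2 / (fs * n)
    scale = np.full(k.size, 2.0)
    scale[0] = 1.0
    if n % 2 == 0:
        scale[-1] = 1.0
    return k * fs / n, psd * scale


def windows_per_episode(lengths, trace_len) -> list[int]:
    """Number of non-overlapping trace_len windows tiled from each
    episode onset (brute counting)."""
    out = []
    for length in lengths:
        c = 0
        t = 0.0
        while t + trace_len <= length + 1e-9:
            c += 1
            t += trace_len
        out.append(c)
    return out


def powerlaw_fraction(alpha, band, total) -> float:
    """Closed-form integral of f**-alpha over band / total."""
    f1, f2 = band
    t1, t2 = total
    if alpha == 1.0:
        return math.log(f2 / f1) / math.log(t2 / t1)
    a = alpha - 1.0
    return (f1**-a - f2**-a) / (t1**-a - t2**-a)
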