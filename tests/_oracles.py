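"""Independent brute-force oracles used to freeze expected values.

Everything here deliberately avoids the library code paths it checks:
combinatorics via ``math.comb``, slopes via ``np.polyfit``, survival via
direct counting, significance via permutation.
"""

from __future__ import annotations

from math import comb

import numpy as np


def fisher_two_sided_oracle(a: int, b: int, c: int, d: int) -> float:
    """Full hypergeometric enumeration with exact rational-ish arithmetic."""
    n1, n2, m1 = a + b, c + d, a + c
    n = n1 + n2
    denom = comb(n, m1)

    def pk(k: int) -> float:
        return comb(n1, k) * comb(n2, m1 - k) / denom

    p_obs = pk(a)
    total = 0.0
    for k in range(max(0, m1 - n2), min(m1, n1) + 1):
        p = pk(k)
        if p <= p_obs * (1 + 1e-7):
            total += p
    return min(1.0, total)


def fisher_one_sided_oracle(a: int, b: int, c: int, d: int,
                            alternative: str = "greater") -> float:
    n1, n2, m1 = a + b, c + d, a + c
    n = n1 + n2
    denom = comb(n, m1)
    ks = range(max(0, m1 - n2), min(m1, n1) + 1)
    if alternative == "greater":
        return sum(comb(n1, k) * comb(n2, m1 - k) for k in ks if k >= a) / denom
    return sum(comb(n1, k) * comb(n2, m1 - k) for k in ks if k <= a) / denom


def boschloo_oracle(a: int, b: int, c: int, d: int, n_grid: int = 1001) -> float:
    """Direct enumeration of the unconditional test at small n (two-sided by
    doubling).  Statistic = one-sided Fisher p in the observed direction."""
    n1, n2 = a + b, c + d
    direction = "greater" if a / n1 >= c / n2 else "less"
    stat_obs = fisher_one_sided_oracle(a, b, c, d, direction)
    stats_tab = np.array([[fisher_one_sided_oracle(x1, n1 - x1, x2, n2 - x2, direction)
                           for x2 in range(n2 + 1)] for x1 in range(n1 + 1)])
    extreme = stats_tab <= stat_obs * (1 + 1e-12)
    b1 = np.array([[comb(n1, x1) for x1 in range(n1 + 1)]])
    b2 = np.array([[comb(n2, x2) for x2 in range(n2 + 1)]])
    best = 0.0
    for pi in np.linspace(1e-6, 1 - 1e-6, n_grid):
        pmf1 = b1 * pi ** np.arange(n1 + 1) * (1 - pi) ** (n1 - np.arange(n1 + 1))
        pmf2 = b2 * pi ** np.arange(n2 + 1) * (1 - pi) ** (n2 - np.arange(n2 + 1))
        best = max(best, float((pmf1.T @ pmf2)[extreme].sum()))
    return min(1.0, 2 * best)


def steepest_slope_oracle(times: np.ndarray, areas: np.ndarray,
                          window_points: int) -> tuple[float, tuple[float, float]]:
    """Exhaustive window enumeration with np.polyfit."""
    best = None
    for i in range(len(times) - window_points + 1):
        tw = times[i:i + window_points]
        slope = np.polyfit(tw, areas[i:i + window_points], 1)[0]
        if best is None or slope < best[0]:
            best = (float(slope), (float(tw[0]), float(tw[-1])))
    return best


def empirical_survival(times: np.ndarray, t: float) -> float:
    """Fraction of observations strictly exceeding t (no censoring)."""
    return float(np.mean(np.asarray(times) > t))


def permutation_logrank_p(times_a, censored_a, times_b, censored_b,
                          statistic_fn, n_perm: int = 2000,
                          seed: int = 0) -> float:
    """Permutation p-value for any two-sample statistic (label shuffling)."""
    rng = np.random.default_rng(seed)
    times = np.concatenate([times_a, times_b])
    cens = np.concatenate([censored_a, censored_b]).astype(bool)
    na = len(times_a)
    obs = statistic_fn(times_a, censored_a, times_b, censored_b)
    count = 0
    idx = np.arange(len(times))
    for _ in range(n_perm):
        rng.shuffle(idx)
        ta, ca = times[idx[:na]], cens[idx[:na]]
        tb, cb = times[idx[na:]], cens[idx[na:]]
        if statistic_fn(ta, ca, tb, cb) >= obs - 1e-12:
            count += 1
    return (count + 1) / (n_perm + 1)
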