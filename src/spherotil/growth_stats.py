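"""Caliper tumor-growth quantification and the bespoke cohort statistics.

Volumes use the modified elliptical formula ``V = 0.5 * L * W**2``.  The
growth-rate statistic R has units of 1/time and is computed as the relative
cell-number change per hour; the cells-per-mm^3 constant ``QG`` cancels
algebraically but is retained for explicit-unit bookkeeping.  Exact 2x2
inference is implemented from first principles (hypergeometric enumeration for
Fisher; unconditional nuisance-maximized Boschloo).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

#: cells per mm^3 of tumor (used only for explicit-unit logging; cancels in R)
QG = 2.76e5

#: default cell-division interval in hours entering the R-value denominator
DT_H = 8.0

#: Altman-nomogram constant for p < 0.01 at 80% power
CP_POWER = 11.7


@dataclass
class TumorCourse:
    """Caliper length/width series for one mouse."""

    mouse: str
    group: str
    days: np.ndarray
    length_mm: np.ndarray
    width_mm: np.ndarray
    start_day: float = 12.0

    def __post_init__(self) -> None:
        self.days = np.asarray(self.days, dtype=float)
        self.length_mm = np.asarray(self.length_mm, dtype=float)
        self.width_mm = np.asarray(self.width_mm, dtype=float)
        if not (len(self.days) == len(self.length_mm) == len(self.width_mm)):
            raise ValueError("days, length and width must have equal length")
        if np.any(np.diff(self.days) <= 0):
            raise ValueError("days must be strictly increasing")
        if np.any(self.length_mm < 0) or np.any(self.width_mm < 0):
            raise ValueError("caliper dimensions must be non-negative")
        # convention: length is the larger caliper dimension
        lo = np.minimum(self.length_mm, self.width_mm)
        hi = np.maximum(self.length_mm, self.width_mm)
        self.length_mm, self.width_mm = hi, lo

    @property
    def volume_mm3(self) -> np.ndarray:
        return elliptical_volume(self.length_mm, self.width_mm)


@dataclass
class GrowthStats:
    mouse: str
    group: str
    v_initial: float
    v_final: float
    ratio_final_initial: float
    r_per_h: float
    responder: bool
    relapsed: bool
    stable_remission: bool


def elliptical_volume(length_mm, width_mm):
    """Modified elliptical volume ``0.5 * L * W**2`` in mm^3."""
    length_mm = np.asarray(length_mm, dtype=float)
    width_mm = np.asarray(width_mm, dtype=float)
    if np.any(length_mm < 0) or np.any(width_mm < 0):
        raise ValueError("caliper dimensions must be non-negative")
    out = 0.5 * length_mm * width_mm**2
    return float(out) if out.ndim == 0 else out


def r_value(v_initial: float, v_final: float, dt_h: float = DT_H,
            explicit_qg: bool = False) -> float:
    """Growth-rate statistic R (1/h): relative cell-number change per hour.

    With cell number ``c = QG * V``, ``R = (dc/dt) / c = (V_f - V_i) / (V_i * dt)``;
    QG cancels.  ``explicit_qg=True`` computes the same quantity through the
    cell-number route without cancellation (identity check / unit bookkeeping).
    """
    if v_initial <= 0:
        raise ValueError("initial volume must be positive")
    if dt_h <= 0:
        raise ValueError("dt must be positive")
    if explicit_qg:
        c = QG * v_initial
        dc = QG * v_final - QG * v_initial
        return (dc / dt_h) / c
    return (v_final - v_initial) / (v_initial * dt_h)


def course_r_value(course: TumorCourse, window_days: tuple[float, float] = (12.0, 16.0),
                   dt_h: float = DT_H) -> float:
    """R over the early-growth window (default days 12-16), from the first and
    last measurements falling inside the window."""
    v = course.volume_mm3
    lo, hi = window_days
    idx = np.where((course.days >= lo) & (course.days <= hi))[0]
    if len(idx) < 2:
        raise ValueError(f"course {course.mouse}: <2 measurements in window {window_days}")
    return r_value(v[idx[0]], v[idx[-1]], dt_h=dt_h)


def classify_course(course: TumorCourse, remission_mm: float = 5.0,
                    remission_days: float = 8.0) -> GrowthStats:
    """Responder / relapse / stable-remission flags for one course.

    responder: volume falls below the start-of-treatment volume on >= 2
    consecutive measurements after treatment start.  relapsed: a responder
    whose volume later reaches >= the start volume.  stable_remission: both
    caliper dimensions stay < ``remission_mm`` over a span >= ``remission_days``.
    """
    if len(course.days) < 3:
        raise ValueError("need >= 3 measurements to classify a course")
    v = course.volume_mm3
    post = course.days >= course.start_day
    if not post.any():
        raise ValueError("no measurements at or after treatment start")
    i0 = int(np.argmax(post))
    v_start = v[i0]
    below = (v < v_start) & post
    # indices (after start) with >= 2 consecutive sub-start measurements
    responder = False
    first_resp = None
    for i in range(i0, len(v) - 1):
        if below[i] and below[i + 1]:
            responder = True
            first_resp = i
            break
    relapsed = False
    if responder:
        relapsed = bool(np.any(v[first_resp + 1:] >= v_start))

    small = (course.length_mm < remission_mm) & (course.width_mm < remission_mm) & post
    stable = False
    run_start = None
    for i, s in enumerate(small):
        if s:
            if run_start is None:
                run_start = i
            if course.days[i] - course.days[run_start] >= remission_days:
                stable = True
                break
        else:
            run_start = None

    return GrowthStats(
        mouse=course.mouse, group=course.group,
        v_initial=float(v_start), v_final=float(v[-1]),
        ratio_final_initial=float(v[-1] / v_start) if v_start > 0 else math.nan,
        r_per_h=(course_r_value(course)
                 if ((course.days >= 12) & (course.days <= 16)).sum() >= 2
                 else math.nan),
        responder=responder, relapsed=relapsed, stable_remission=stable,
    )


# ---------------------------------------------------------------------------
# exact 2x2 inference


@dataclass(frozen=True)
class Contingency2x2:
    """Counts (a, b; c, d): rows = groups, columns = (event, no event)."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for v in (self.a, self.b, self.c, self.d):
            if int(v) != v or v < 0:
                raise ValueError("counts must be non-negative integers")
        if self.a + self.b + self.c + self.d < 1:
            raise ValueError("table total must be >= 1")

    @property
    def row_sums(self) -> tuple[int, int]:
        return self.a + self.b, self.c + self.d

    @property
    def col_sums(self) -> tuple[int, int]:
        return self.a + self.c, self.b + self.d


def _as_table(table) -> Contingency2x2:
    if isinstance(table, Contingency2x2):
        return table
    (a, b), (c, d) = table
    return Contingency2x2(int(a), int(b), int(c), int(d))


def fisher_exact(table) -> float:
    """Two-sided Fisher exact p by full hypergeometric enumeration.

    With margins fixed, sums P(X = k) over all admissible k whose table
    probability does not exceed the observed one (within rel. tol. 1e-7).
    """
    t = _as_table(table)
    n1, n2 = t.row_sums
    m1, _ = t.col_sums
    n = n1 + n2
    if 0 in (n1, n2) or 0 in t.col_sums:
        return 1.0
    k_obs = t.a
    k_min, k_max = max(0, m1 - n2), min(m1, n1)
    ks = np.arange(k_min, k_max + 1)
    pmf = stats.hypergeom.pmf(ks, n, m1, n1)
    p_obs = stats.hypergeom.pmf(k_obs, n, m1, n1)
    return float(min(1.0, pmf[pmf <= p_obs * (1 + 1e-7)].sum()))


def fisher_exact_one_sided(table, alternative: str = "less") -> float:
    """One-sided Fisher p for the first row's event proportion."""
    t = _as_table(table)
    n1, n2 = t.row_sums
    m1, _ = t.col_sums
    n = n1 + n2
    if alternative == "less":
        return float(stats.hypergeom.cdf(t.a, n, m1, n1))
    if alternative == "greater":
        return float(stats.hypergeom.sf(t.a - 1, n, m1, n1))
    raise ValueError("alternative must be 'less' or 'greater'")


def boschloo(table, grid_size: int = 200, alternative: str = "two-sided") -> float:
    """Exact unconditional (Boschloo) p for a 2x2 table.

    Statistic = one-sided Fisher p (in the direction of the observed effect);
    the p-value maximizes, over a grid of the common nuisance success
    probability, the binomial probability of all tables at least as extreme.
    Two-sided p doubles the one-sided result, capped at 1.
    """
    if grid_size < 10:
        raise ValueError("grid_size must be >= 10")
    t = _as_table(table)
    n1, n2 = t.row_sums
    if n1 == 0 or n2 == 0:
        raise ValueError("both row margins must be positive")
    p1 = t.a / n1
    p2 = t.c / n2
    direction = "greater" if p1 >= p2 else "less"

    # statistic for every table (x1, x2) with the observed row sizes
    x1 = np.arange(n1 + 1)[:, None]
    x2 = np.arange(n2 + 1)[None, :]
    m1 = x1 + x2
    n = n1 + n2
    if direction == "greater":
        stat = stats.hypergeom.sf(x1 - 1, n, m1, n1)
    else:
        stat = stats.hypergeom.cdf(x1, n, m1, n1)
    stat_obs = stat[t.a, t.c]
    extreme = stat <= stat_obs * (1 + 1e-12)

    pis = np.linspace(1e-6, 1 - 1e-6, grid_size)
    p_max = 0.0
    for pi in pis:
        pmf1 = stats.binom.pmf(np.arange(n1 + 1), n1, pi)[:, None]
        pmf2 = stats.binom.pmf(np.arange(n2 + 1), n2, pi)[None, :]
        p_max = max(p_max, float((pmf1 * pmf2)[extreme].sum()))
    if alternative == "one-sided":
        return min(1.0, p_max)
    return min(1.0, 2.0 * p_max)


def prop_ztest(x1: int, n1: int, x2: int, n2: int) -> tuple[float, float]:
    """Pooled two-proportion z statistic and two-sided normal p."""
    if n1 <= 0 or n2 <= 0:
        raise ValueError("group sizes must be positive")
    if not (0 <= x1 <= n1 and 0 <= x2 <= n2):
        raise ValueError("counts must lie within group sizes")
    p1, p2 = x1 / n1, x2 / n2
    p_pool = (x1 + x2) / (n1 + n2)
    se = math.sqrt(p_pool * (1 - p_pool) * (1 / n1 + 1 / n2))
    if se == 0:
        return 0.0, 1.0
    z = (p1 - p2) / se
    p = 2 * stats.norm.sf(abs(z))
    return float(z), float(p)


def sample_size(d: float, cp_power: float = CP_POWER) -> int:
    """Mice per group: ``ceil((2 / d**2) * cp_power)``, floored at 1."""
    if d <= 0:
        raise ValueError("standardized difference must be positive")
    return max(1, math.ceil((2.0 / d**2) * cp_power))


def exclude_outliers(courses: list[TumorCourse],
                     window_days: tuple[float, float] = (12.0, 16.0)) -> list[TumorCourse]:
    """Drop courses with early growth rate R > mean(R) + 1 SD (one-sided).

    With zero spread (identical courses) nothing is excluded.
    """
    if not courses:
        return []
    rs = np.array([course_r_value(c, window_days) for c in courses])
    sd = rs.std(ddof=1) if len(rs) > 1 else 0.0
    if sd == 0:
        return list(courses)
    cut = rs.mean() + sd
    return [c for c, r in zip(courses, rs) if r <= cut]
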