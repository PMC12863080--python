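"""Statistical primitives used across the pipeline.

Implemented here rather than delegated wholesale so the small-sample
behaviour is explicit and under test: the Wilcoxon tests switch to
exact null distributions at small n (enumeration/DP), zero differences
are discarded (classic Wilcoxon, not Pratt), and ties are handled by
mid-ranks with the usual variance corrections.  Only distribution tail
functions (normal, t, chi-square) come from scipy.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as _sps

__all__ = [
    "TestResult",
    "wilcoxon_signed_rank",
    "wilcoxon_rank_sum",
    "spearman",
    "chi2_2x2",
    "bh_adjust",
    "fit_quadratic",
]

# largest n for the exact signed-rank null; above this the normal
# approximation with tie/continuity correction takes over
EXACT_SIGNED_RANK_MAX_N = 25
# enumeration budget for the exact rank-sum null
EXACT_RANK_SUM_MAX_COMBOS = 300_000


@dataclass
class TestResult:
    statistic: float
    p_value: float
    n: int
    method: str
    direction: str | None = None
    note: str = ""

    def __post_init__(self) -> None:
        if not (math.isnan(self.p_value) or 0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value out of range: {self.p_value}")


def _midranks(values: np.ndarray) -> np.ndarray:
    """Average ranks (1-based) with ties sharing their mid-rank."""
    order = np.argsort(values, kind="mergesort")
    ranks = np.empty(len(values), dtype=float)
    sorted_vals = values[order]
    i = 0
    while i < len(values):
        j = i
        while j + 1 < len(values) and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        ranks[order[i : j + 1]] = 0.5 * (i + j) + 1.0
        i = j + 1
    return ranks


def _tie_groups(values: np.ndarray) -> np.ndarray:
    _, counts = np.unique(values, return_counts=True)
    return counts


def _signed_rank_exact_p(w_plus: float, n: int) -> float:
    """Two-sided p by full enumeration of the W+ null (no ties).

    The null distribution of W+ is the distribution of subset sums of
    {1..n} with each rank included independently w.p. 1/2; computed by
    polynomial DP in O(n^3).
    """
    m = n * (n + 1) // 2
    counts = np.zeros(m + 1, dtype=np.float64)
    counts[0] = 1.0
    for r in range(1, n + 1):
        counts[r:] += counts[: m + 1 - r].copy()
    total = counts.sum()  # == 2**n
    w = int(round(w_plus))
    lower = counts[: w + 1].sum() / total
    upper = counts[w:].sum() / total
    return min(1.0, 2.0 * min(lower, upper))


def wilcoxon_signed_rank(values, mu: float = 0.0) -> TestResult:
    """One-sample Wilcoxon signed-rank test of location against ``mu``.

    Zero differences are discarded. Exact two-sided p for n <= 25
    without ties; otherwise normal approximation with tie and
    continuity corrections. ``direction`` reports which side of ``mu``
    the sample median falls on.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("empty sample")
    d = values - mu
    direction = "less" if np.median(values) < mu else "greater"
    d = d[d != 0.0]
    n = d.size
    if n == 0:
        return TestResult(0.0, 1.0, 0, "wilcoxon-signed-rank (all zeros)", direction=None)
    absd = np.abs(d)
    ranks = _midranks(absd)
    w_plus = float(ranks[d > 0].sum())
    has_ties = len(np.unique(absd)) < n
    if n <= EXACT_SIGNED_RANK_MAX_N and not has_ties:
        p = _signed_rank_exact_p(w_plus, n)
        return TestResult(w_plus, p, n, "wilcoxon-signed-rank exact", direction=direction)
    mean_w = n * (n + 1) / 4.0
    tie_counts = _tie_groups(absd)
    var_w = n * (n + 1) * (2 * n + 1) / 24.0 - ((tie_counts**3 - tie_counts).sum()) / 48.0
    if var_w <= 0:
        return TestResult(w_plus, 1.0, n, "wilcoxon-signed-rank degenerate", direction=direction)
    cc = 0.5 if w_plus != mean_w else 0.0
    z = (w_plus - mean_w - math.copysign(cc, w_plus - mean_w)) / math.sqrt(var_w)
    p = min(1.0, 2.0 * _sps.norm.sf(abs(z)))
    return TestResult(w_plus, p, n, "wilcoxon-signed-rank normal-approx", direction=direction)


def _rank_sum_exact_p(ranks: np.ndarray, n1: int, u1: float) -> float:
    """Two-sided p by enumerating all rank assignments to group 1."""
    all_idx = range(len(ranks))
    offset = n1 * (n1 + 1) / 2.0
    us = []
    for combo in itertools.combinations(all_idx, n1):
        us.append(ranks[list(combo)].sum() - offset)
    us = np.asarray(us)
    total = len(us)
    lower = np.count_nonzero(us <= u1 + 1e-9) / total
    upper = np.count_nonzero(us >= u1 - 1e-9) / total
    return min(1.0, 2.0 * min(lower, upper))


def wilcoxon_rank_sum(x, y) -> TestResult:
    """Two-sample Wilcoxon rank-sum (Mann-Whitney U), two-sided.

    Exact null by enumeration for small groups; otherwise normal
    approximation with tie and continuity corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    n1, n2 = x.size, y.size
    combined = np.concatenate([x, y])
    ranks = _midranks(combined)
    r1 = float(ranks[:n1].sum())
    u1 = r1 - n1 * (n1 + 1) / 2.0
    direction = "greater" if u1 > n1 * n2 / 2.0 else "less"
    if min(n1, n2) <= 8 and math.comb(n1 + n2, n1) <= EXACT_RANK_SUM_MAX_COMBOS:
        p = _rank_sum_exact_p(ranks, n1, u1)
        return TestResult(u1, p, n1 + n2, "wilcoxon-rank-sum exact", direction=direction)
    mean_u = n1 * n2 / 2.0
    N = n1 + n2
    tie_counts = _tie_groups(combined)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (N * (N - 1)) if N > 1 else 0.0
    var_u = n1 * n2 / 12.0 * ((N + 1) - tie_term)
    if var_u <= 0:
        return TestResult(u1, 1.0, N, "wilcoxon-rank-sum degenerate", direction=direction)
    cc = 0.5 if u1 != mean_u else 0.0
    z = (u1 - mean_u - math.copysign(cc, u1 - mean_u)) / math.sqrt(var_u)
    p = min(1.0, 2.0 * _sps.norm.sf(abs(z)))
    return TestResult(u1, p, N, "wilcoxon-rank-sum normal-approx", direction=direction)


def spearman(x, y) -> TestResult:
    """Spearman rank correlation: Pearson on mid-ranks, t-approximation p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    n = x.size
    if n < 3:
        raise ValueError("need n >= 3")
    rx, ry = _midranks(x), _midranks(y)
    sx, sy = rx.std(), ry.std()
    if sx == 0 or sy == 0:
        return TestResult(float("nan"), float("nan"), n, "spearman undefined",
                          note="zero variance in ranks")
    rho = float(np.corrcoef(rx, ry)[0, 1])
    rho = max(-1.0, min(1.0, rho))
    if abs(rho) == 1.0:
        p = 0.0
    else:
        t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
        p = min(1.0, 2.0 * _sps.t.sf(abs(t), n - 2))
    return TestResult(rho, p, n, "spearman t-approx",
                      direction="positive" if rho >= 0 else "negative")


def chi2_2x2(a: float, b: float, c: float, d: float) -> TestResult:
    """Pearson chi-square on a 2x2 table [[a, b], [c, d]], df=1, no continuity correction."""
    obs = np.array([[a, b], [c, d]], dtype=float)
    if (obs < 0).any():
        raise ValueError("counts must be non-negative")
    row = obs.sum(axis=1)
    col = obs.sum(axis=0)
    total = obs.sum()
    if total == 0 or (row == 0).any() or (col == 0).any():
        return TestResult(0.0, 1.0, int(total), "chi2-2x2 degenerate",
                          note="zero marginal")
    expected = np.outer(row, col) / total
    chi2 = float(((obs - expected) ** 2 / expected).sum())
    p = float(_sps.chi2.sf(chi2, df=1))
    note = "low expected count" if (expected < 5).any() else ""
    return TestResult(chi2, p, int(total), "chi2-2x2", note=note)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def fit_quadratic(x, y) -> tuple[float, float, float]:
    """Least squares fit of y = a + b*x + c*x**2; returns (a, b, c)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if len(np.unique(x)) < 3:
        raise ValueError("need >= 3 distinct x values for a quadratic fit")
    design = np.column_stack([np.ones_like(x), x, x * x])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    a, b, c = (float(v) for v in coef)
    return a, b, c
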