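"""Rank and correlation statistics used throughout the pipeline.

* Mann-Whitney U with an exact, tie-aware null distribution (full
  enumeration over group labelings, computed by dynamic programming) for
  pooled sample sizes up to 25, and a tie-corrected normal approximation
  beyond that.
* One-tailed Pearson and Spearman correlations with t-distribution p-values.
* Through-origin Pearson correlation for independent contrasts (contrasts
  have expectation zero, so no intercept; df = n - 1).
* Meta-combination across studies: Fisher z-transformed correlations
  weighted by (n_i - 3), and Stouffer's combined probability.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .model import CorrelationError, MitoError

__all__ = [
    "RankTestResult",
    "CorrelationResult",
    "MetaResult",
    "mann_whitney_u",
    "pearson_one_tailed",
    "spearman_one_tailed",
    "pearson_through_origin",
    "combine_correlations",
]

EXACT_LIMIT = 25  # pooled size at or below which the exact U null is used


@dataclass(frozen=True)
class RankTestResult:
    U: float
    n1: int
    n2: int
    p_one_tailed: float
    p_two_tailed: float
    method: str  # "exact" | "normal_approx"

    def to_dict(self) -> dict:
        return {"U": self.U, "n1": self.n1, "n2": self.n2,
                "p_one_tailed": self.p_one_tailed,
                "p_two_tailed": self.p_two_tailed, "method": self.method}


@dataclass(frozen=True)
class CorrelationResult:
    method: str  # "pearson" | "spearman" | "pearson_through_origin"
    r: float
    n: int
    df: int
    t: float
    p_one_tailed: float
    tail: str = "negative"

    def to_dict(self) -> dict:
        return {"method": self.method, "r": self.r, "n": self.n, "df": self.df,
                "t": self.t, "p_one_tailed": self.p_one_tailed, "tail": self.tail}


@dataclass(frozen=True)
class MetaResult:
    studies: tuple[tuple[str, float, int, float], ...]  # (label, r, n, p)
    r_weighted: float
    Z_stouffer: float
    p_combined: float
    k: int

    def to_dict(self) -> dict:
        return {"k": self.k, "r_weighted": self.r_weighted,
                "Z_stouffer": self.Z_stouffer, "p_combined": self.p_combined,
                "studies": [list(s) for s in self.studies]}


# ---------------------------------------------------------------------------
# Mann-Whitney U
# ---------------------------------------------------------------------------

def _exact_rank_sum_counts(doubled_ranks: Sequence[int], n1: int) -> np.ndarray:
    """Counts of labelings by doubled rank-sum of group 1.

    ``counts[k, s]`` after the DP = number of ways to pick ``k`` of the
    pooled observations with doubled-rank total ``s``; equivalent to full
    enumeration of the C(N, n1) group labelings.
    """
    max_sum = int(sum(doubled_ranks))
    counts = np.zeros((n1 + 1, max_sum + 1), dtype=float)
    counts[0, 0] = 1.0
    for r in doubled_ranks:
        counts[1:, r:] += counts[:-1, :-r or None].copy() if r else counts[:-1, :]
    return counts[n1]


def mann_whitney_u(
    group_a: Sequence[float], group_b: Sequence[float]
) -> RankTestResult:
    """Mann-Whitney U test, exact (tie-aware) for pooled n <= 25.

    U is the smaller of U_a and U_b, where
    ``U_a = #{(a, b): a > b} + 0.5 * #ties``, computed via rank sums. Both
    tails are reported: the one-tailed p is the probability of a rank sum at
    least as extreme in the smaller-U direction, the two-tailed p adds the
    reflected opposite tail.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise MitoError("mann_whitney_u: both groups must be nonempty")
    n1, n2 = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    r_a = float(ranks[:n1].sum())
    u_a = r_a - n1 * (n1 + 1) / 2.0
    u_b = n1 * n2 - u_a
    u = min(u_a, u_b)

    if n1 + n2 <= EXACT_LIMIT:
        doubled = np.rint(2 * ranks).astype(int)
        dist = _exact_rank_sum_counts(doubled, n1)
        total = math.comb(n1 + n2, n1)
        sums = np.arange(dist.size)
        # doubled rank-sum s  <->  U_a = s/2 - n1(n1+1)/2
        u_vals = sums / 2.0 - n1 * (n1 + 1) / 2.0
        p_low = float(dist[u_vals <= u_a + 1e-9].sum()) / total
        p_high = float(dist[u_vals >= u_a - 1e-9].sum()) / total
        p_one = min(p_low, p_high)
        # reflection rule: add the opposite tail at the mirrored U value
        if u_a <= u_b:
            p_two = p_low + float(dist[u_vals >= u_b - 1e-9].sum()) / total
        else:
            p_two = p_high + float(dist[u_vals <= u_b + 1e-9].sum()) / total
        p_two = min(1.0, p_two)
        method = "exact"
    else:
        n = n1 + n2
        _, tie_counts = np.unique(pooled, return_counts=True)
        tie_term = float(((tie_counts**3 - tie_counts)).sum()) / (n * (n - 1))
        var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
        if var <= 0:
            raise MitoError("mann_whitney_u: zero variance (all values tied)")
        z = (u_a - n1 * n2 / 2.0) / math.sqrt(var)
        p_one = float(sps.norm.sf(abs(z)))
        p_two = min(1.0, 2 * p_one)
        method = "normal_approx"
    return RankTestResult(U=u, n1=n1, n2=n2, p_one_tailed=p_one,
                          p_two_tailed=p_two, method=method)


# ---------------------------------------------------------------------------
# correlations
# ---------------------------------------------------------------------------

def _tail_p(t: float, df: int, tail: str) -> float:
    if tail == "negative":
        return float(sps.t.cdf(t, df))
    if tail == "positive":
        return float(sps.t.sf(t, df))
    raise MitoError(f"unknown tail {tail!r}")


def _check_xy(x, y, min_n: int = 3) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise MitoError("x and y must be equal-length 1-D sequences")
    if x.size < min_n:
        raise MitoError(f"need at least {min_n} observations, got {x.size}")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise MitoError("non-finite values in correlation input")
    return x, y


def _t_from_r(r: float, df: int) -> float:
    if abs(r) >= 1.0:
        return math.copysign(math.inf, r)
    return r * math.sqrt(df / (1.0 - r * r))


def pearson_one_tailed(x, y, tail: str = "negative") -> CorrelationResult:
    """Product-moment correlation with a one-tailed t test on n-2 df."""
    x, y = _check_xy(x, y)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise CorrelationError("undefined correlation: zero variance input")
    r = float(np.corrcoef(x, y)[0, 1])
    n = x.size
    df = n - 2
    t = _t_from_r(r, df)
    return CorrelationResult("pearson", r, n, df, t, _tail_p(t, df, tail), tail)


def spearman_one_tailed(x, y, tail: str = "negative") -> CorrelationResult:
    """Spearman rank correlation (mean ranks for ties), t approximation."""
    x, y = _check_xy(x, y)
    rx, ry = sps.rankdata(x), sps.rankdata(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        raise CorrelationError("undefined correlation: constant ranks")
    r = float(np.corrcoef(rx, ry)[0, 1])
    n = x.size
    df = n - 2
    t = _t_from_r(r, df)
    return CorrelationResult("spearman", r, n, df, t, _tail_p(t, df, tail), tail)


def pearson_through_origin(x, y, tail: str = "negative") -> CorrelationResult:
    """Correlation constrained through the origin; df = n - 1.

    Appropriate for independent contrasts, whose expectation is zero and
    whose sign is arbitrary (flipping both members of a pair leaves the
    statistic unchanged).
    """
    x, y = _check_xy(x, y)
    sxx = float(x @ x)
    syy = float(y @ y)
    if sxx == 0 or syy == 0:
        raise CorrelationError("undefined correlation: zero sum of squares")
    r = float(x @ y) / math.sqrt(sxx * syy)
    r = max(-1.0, min(1.0, r))
    n = x.size
    df = n - 1
    t = _t_from_r(r, df)
    return CorrelationResult("pearson_through_origin", r, n, df, t,
                             _tail_p(t, df, tail), tail)


# ---------------------------------------------------------------------------
# meta-analysis
# ---------------------------------------------------------------------------

def combine_correlations(
    studies: Sequence[tuple[str, float, int, float]],
    weighted_stouffer: bool = False,
) -> MetaResult:
    """Combine per-tRNA correlations across studies.

    ``r_weighted = tanh(sum (n_i - 3) atanh(r_i) / sum (n_i - 3))`` and
    ``Z = sum Phi^-1(1 - p_i) / sqrt(k)`` (optionally weighted by
    ``sqrt(n_i - 3)``); studies with n < 4 are dropped with a warning, and
    |r| = 1 is rejected (infinite z).
    """
    kept = []
    for label, r, n, p in studies:
        if n < 4:
            warnings.warn(f"study {label!r} dropped: n={n} < 4", stacklevel=2)
            continue
        if abs(r) >= 1.0:
            raise MitoError(f"study {label!r}: |r| = 1 gives infinite Fisher z")
        kept.append((str(label), float(r), int(n), float(p)))
    if not kept:
        raise MitoError("no usable studies (all n < 4)")
    k = len(kept)
    w = np.array([n - 3 for _, _, n, _ in kept], dtype=float)
    z_r = np.array([math.atanh(r) for _, r, _, _ in kept])
    r_weighted = float(math.tanh(float(w @ z_r) / float(w.sum())))
    z_p = sps.norm.isf([p for _, _, _, p in kept])  # Phi^-1(1 - p)
    if weighted_stouffer:
        sw = np.sqrt(w)
        Z = float((sw @ z_p) / math.sqrt(float(w.sum())))
    else:
        Z = float(z_p.sum() / math.sqrt(k))
    p_combined = float(sps.norm.sf(Z))
    return MetaResult(studies=tuple(kept), r_weighted=r_weighted,
                      Z_stouffer=Z, p_combined=p_combined, k=k)
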