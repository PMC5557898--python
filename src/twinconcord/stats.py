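"""Inferential statistics for twin-pair analyses.

Exact tests (Fisher's exact test on 2x2 tables, the Wilcoxon signed-rank
test at small n) are computed with integer / dynamic-programming
arithmetic rather than asymptotic approximations, so that the p-values on
the small embryo cohorts typical of this field carry no enumeration
error.  Routine summaries (Pearson r, t-tests, medians) delegate to
numpy/scipy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from fractions import Fraction
from typing import Literal, Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "ContingencyTable2x2",
    "FisherResult",
    "fisher_exact_2x2",
    "WilcoxonResult",
    "wilcoxon_signed_rank",
    "wilcoxon_order_sensitivity",
    "percentage",
    "pearson_r",
    "two_sample_t",
    "median",
    "STAGE_ORDER",
    "encode_stage",
]

# Ordinal encoding of preimplantation stages; compacted morula and
# blastocyst are distinct levels.
STAGE_ORDER = {
    "one-cell": 1,
    "two-cell": 2,
    "four-cell": 3,
    "eight-cell": 4,
    "morula": 5,
    "blastocyst": 6,
}


def encode_stage(stage: str) -> int:
    """Map a developmental-stage name onto its ordinal level (1..6)."""
    try:
        return STAGE_ORDER[stage]
    except KeyError:
        raise ValueError(f"unknown developmental stage: {stage!r}") from None


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts of a 2x2 table; rows are groups, columns are outcome yes/no."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for v in (self.a, self.b, self.c, self.d):
            if v < 0 or int(v) != v:
                raise ValueError("table entries must be non-negative integers")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("at least one margin must be positive")


@dataclass(frozen=True)
class FisherResult:
    pvalue: float
    point_prob: float
    degenerate: bool
    method: str


def fisher_exact_2x2(
    table: ContingencyTable2x2 | Sequence[Sequence[int]],
    method: Literal["sum-small-p", "double-tail"] = "sum-small-p",
) -> FisherResult:
    """Two-sided Fisher's exact test on a 2x2 table.

    The conditional distribution given the margins is hypergeometric; the
    two-sided p-value sums the point probabilities of every table (with
    the observed margins) whose probability does not exceed that of the
    observed table.  All arithmetic is exact (integer numerators over a
    common binomial denominator), so probability ties are resolved
    exactly rather than within floating-point tolerance.

    Degenerate tables (a zero row or column margin) admit a single
    configuration; p = 1 is returned with ``degenerate=True``.

    Parameters
    ----------
    table:
        A :class:`ContingencyTable2x2` or nested sequence ``[[a, b], [c, d]]``.
    method:
        ``"sum-small-p"`` (default) sums all tables at most as probable as
        the observed one; ``"double-tail"`` doubles the smaller one-sided
        tail probability (capped at 1).
    """
    if not isinstance(table, ContingencyTable2x2):
        (a, b), (c, d) = table
        table = ContingencyTable2x2(int(a), int(b), int(c), int(d))
    a, b, c, d = table.a, table.b, table.c, table.d
    r1, r2 = a + b, c + d
    c1, c2 = a + c, b + d
    n = r1 + r2
    if min(r1, r2, c1, c2) == 0:
        return FisherResult(pvalue=1.0, point_prob=1.0, degenerate=True, method=method)

    k_min = max(0, c1 - r2)
    k_max = min(r1, c1)
    denom = math.comb(n, c1)
    weights = {k: math.comb(r1, k) * math.comb(r2, c1 - k) for k in range(k_min, k_max + 1)}
    w_obs = weights[a]
    point = float(Fraction(w_obs, denom))

    if method == "sum-small-p":
        num = sum(w for w in weights.values() if w <= w_obs)
        p = Fraction(num, denom)
    elif method == "double-tail":
        lower = sum(w for k, w in weights.items() if k <= a)
        upper = sum(w for k, w in weights.items() if k >= a)
        p = 2 * Fraction(min(lower, upper), denom)
        p = min(p, Fraction(1))
    else:
        raise ValueError(f"unknown method: {method!r}")
    return FisherResult(pvalue=float(p), point_prob=point, degenerate=False, method=method)


@dataclass(frozen=True)
class WilcoxonResult:
    statistic: float  # W+ = sum of ranks of positive differences
    pvalue: float
    n_used: int  # non-zero differences
    n_zero: int
    mode: str  # "exact" or "normal"


def _exact_signed_rank_pvalue(ranks: np.ndarray, w_plus: float) -> float:
    """Exact two-sided p for W+ given the observed (tie-averaged) ranks.

    Enumerates the 2^n equiprobable sign assignments by dynamic
    programming over the achievable rank sums (ranks doubled so that
    tie-averaged half-integer ranks become integers).
    """
    r2 = np.round(ranks * 2).astype(int)
    total = int(r2.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    counts /= counts.sum()
    w2 = int(round(w_plus * 2))
    lower = counts[: w2 + 1].sum()
    upper = counts[w2:].sum()
    return float(min(1.0, 2.0 * min(lower, upper)))


def wilcoxon_signed_rank(
    a: Sequence[float],
    b: Sequence[float],
    exact_limit: int = 25,
) -> WilcoxonResult:
    """Wilcoxon signed-rank test on paired values.

    Zero differences are dropped (Wilcoxon convention) and tied absolute
    differences receive averaged ranks.  The null distribution is
    enumerated exactly for up to ``exact_limit`` non-zero pairs;
    otherwise a normal approximation with tie correction and continuity
    correction is used.

    For unordered twin pairs the sign of each difference depends on
    which member is listed first; ``a``/``b`` are taken in the order
    given (see :func:`wilcoxon_order_sensitivity` for the ordering
    sensitivity analysis).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("a and b must be 1-D sequences of equal length")
    d = a - b
    nz = d != 0
    n_zero = int((~nz).sum())
    d = d[nz]
    n = d.size
    if n == 0:
        raise ValueError("all paired differences are zero; test undefined")
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= exact_limit:
        p = _exact_signed_rank_pvalue(ranks, w_plus)
        mode = "exact"
    else:
        mu = n * (n + 1) / 4.0
        var = n * (n + 1) * (2 * n + 1) / 24.0
        _, tie_counts = np.unique(ranks, return_counts=True)
        var -= (tie_counts**3 - tie_counts).sum() / 48.0
        if var <= 0:
            return WilcoxonResult(w_plus, 1.0, n, n_zero, "normal")
        z = (w_plus - mu - 0.5 * np.sign(w_plus - mu)) / math.sqrt(var)
        p = float(2 * sps.norm.sf(abs(z)))
        p = min(1.0, p)
        mode = "normal"
    return WilcoxonResult(w_plus, p, n, n_zero, mode)


def wilcoxon_order_sensitivity(
    a: Sequence[float],
    b: Sequence[float],
    n_orderings: int = 200,
    seed: int | None = 0,
) -> tuple[float, float, np.ndarray]:
    """p-value range of the signed-rank test over random member orderings.

    Twin members carry no intrinsic order, so each within-pair ordering
    is re-randomized ``n_orderings`` times; returns (min p, max p, all
    p-values).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    rng = np.random.default_rng(seed)
    ps = np.empty(n_orderings)
    for i in range(n_orderings):
        flip = rng.random(a.size) < 0.5
        aa = np.where(flip, b, a)
        bb = np.where(flip, a, b)
        ps[i] = wilcoxon_signed_rank(aa, bb).pvalue
    return float(ps.min()), float(ps.max()), ps


def percentage(k: int, n: int, decimals: int = 1) -> float:
    """100*k/n rounded half-up to ``decimals`` places (e.g. 174/192 -> 90.6)."""
    if n <= 0:
        raise ValueError("n must be positive")
    q = Decimal(1).scaleb(-decimals)
    return float((Decimal(100) * Decimal(k) / Decimal(n)).quantize(q, rounding=ROUND_HALF_UP))


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Pearson correlation; raises on zero variance (undefined)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need at least 3 paired observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("Pearson r undefined for zero-variance input")
    return float(np.corrcoef(x, y)[0, 1])


def two_sample_t(
    x: Sequence[float],
    y: Sequence[float],
    variant: Literal["pooled", "welch"] = "pooled",
) -> tuple[float, float]:
    """Two-sample t-test; returns (t, two-sided p)."""
    res = sps.ttest_ind(np.asarray(x, float), np.asarray(y, float), equal_var=(variant == "pooled"))
    return float(res.statistic), float(res.pvalue)


def median(xs: Sequence[float]) -> float:
    """Median; even-length input gives the mean of the central pair."""
    xs = np.asarray(xs, dtype=float)
    if xs.size == 0:
        raise ValueError("median of empty input")
    return float(np.median(xs))
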