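"""Unordered-pair transcriptome statistics.

Twin members carry no intrinsic order, so per-gene within-pair
comparisons use the ratio E_higher/E_lower (always dividing the larger
expression value by the smaller), which is symmetric in the members and
>= 1.  Genes are then summarized across pairs by the mean and SD of
their ratios and the coefficient of variation CV = SD/mean, which ranks
genes by inter-pair imbalance for enrichment-tool export.  Housekeeping
transcripts are expected to sit near ratio 1; epiblast-program genes
diverge in discordant pairs.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

logger = logging.getLogger(__name__)

#: Housekeeping transcripts used as the stability reference panel.
HOUSEKEEPING_PANEL = ("Actb", "Eef1e1", "Gapdh", "H2afz", "Hprt", "Ppia", "Ubc")

__all__ = [
    "HOUSEKEEPING_PANEL",
    "PairedExpressionMatrix",
    "PairRatioTransformer",
    "pair_ratio",
    "ratio_table",
    "count_exceedance",
    "rank_for_gsea",
    "differential_expression",
    "call_sex_by_xist",
    "group_similarity",
]


@dataclass
class PairedExpressionMatrix:
    """Genes x samples expression values with a sample->pair map.

    ``values`` holds one row per gene and one column per sample; on the
    linear scale all values must be strictly positive.  ``pair_map``
    assigns twin samples to pairs (exactly two samples per pair);
    samples absent from the map (e.g. unmanipulated controls) are
    allowed and ignored by pairwise statistics.  ``group`` optionally
    labels samples (e.g. ``MZ_twin`` vs ``control``).
    """

    values: pd.DataFrame
    pair_map: pd.Series
    group: pd.Series | None = None
    scale: Literal["linear", "log2"] = "linear"

    def __post_init__(self) -> None:
        self.pair_map = pd.Series(self.pair_map)
        unknown = set(self.pair_map.index) - set(self.values.columns)
        if unknown:
            raise ValueError(f"pair_map references unknown samples: {sorted(unknown)}")
        counts = self.pair_map.value_counts()
        bad = counts[counts != 2]
        if not bad.empty:
            raise ValueError(f"every pair needs exactly two samples; offending pairs: {list(bad.index)}")
        if self.scale == "linear" and (self.values.to_numpy() <= 0).any():
            raise ValueError("linear-scale expression values must be strictly positive")
        if self.group is not None:
            self.group = pd.Series(self.group)

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    @property
    def pairs(self) -> list:
        return sorted(self.pair_map.unique())

    def pair_members(self, pair_id) -> tuple[str, str]:
        members = list(self.pair_map.index[self.pair_map == pair_id])
        return members[0], members[1]

    def to_linear(self) -> "PairedExpressionMatrix":
        if self.scale == "linear":
            return self
        return PairedExpressionMatrix(
            np.power(2.0, self.values), self.pair_map, self.group, "linear"
        )

    def to_log2(self) -> "PairedExpressionMatrix":
        if self.scale == "log2":
            return self
        return PairedExpressionMatrix(
            np.log2(self.values), self.pair_map, self.group, "log2"
        )

    def samples_in_group(self, label: str) -> list[str]:
        if self.group is None:
            raise ValueError("matrix carries no group annotation")
        return list(self.group.index[self.group == label])


def pair_ratio(e_a: float, e_b: float, eps: float = 0.0) -> float:
    """Higher/lower expression ratio, symmetric in the two values.

    Returns (max + eps)/(min + eps); equals 1 when the values are equal.
    ``eps`` is a pseudocount for count-like data that may contain zeros
    (microarray-normalized input is strictly positive, so the default
    is 0).
    """
    if e_a < 0 or e_b < 0:
        raise ValueError("expression values must be non-negative")
    lo, hi = (e_a, e_b) if e_a <= e_b else (e_b, e_a)
    if lo + eps == 0:
        raise ValueError("ratio undefined: lower value and pseudocount both zero")
    return (hi + eps) / (lo + eps)


def _pair_ratio_matrix(
    matrix: PairedExpressionMatrix, pairs: Sequence | None, eps: float
) -> pd.DataFrame:
    """Genes x pairs table of higher/lower ratios (linear scale)."""
    lin = matrix.to_linear()
    use_pairs = list(pairs) if pairs is not None else lin.pairs
    cols = {}
    for pid in use_pairs:
        sa, sb = lin.pair_members(pid)
        va = lin.values[sa].to_numpy(dtype=float)
        vb = lin.values[sb].to_numpy(dtype=float)
        lo = np.minimum(va, vb) + eps
        hi = np.maximum(va, vb) + eps
        if (lo == 0).any():
            bad = lin.genes[lo == 0][:5].tolist()
            raise ValueError(f"zero expression in both members with eps=0 (pair {pid}, genes {bad})")
        cols[pid] = hi / lo
    return pd.DataFrame(cols, index=lin.genes)


def ratio_table(
    matrix: PairedExpressionMatrix,
    pairs: Sequence | None = None,
    eps: float = 0.0,
) -> pd.DataFrame:
    """Per-gene mean, sample SD (n-1) and CV of the pair ratios.

    Returns a DataFrame indexed by gene with columns ``mean_ratio``,
    ``sd_ratio`` and ``cv`` (= sd/mean); CV is 0 iff all pair ratios of
    a gene are equal.
    """
    ratios = _pair_ratio_matrix(matrix, pairs, eps)
    mean = ratios.mean(axis=1)
    sd = ratios.std(axis=1, ddof=1) if ratios.shape[1] > 1 else pd.Series(0.0, index=ratios.index)
    sd = sd.fillna(0.0)
    return pd.DataFrame({"mean_ratio": mean, "sd_ratio": sd, "cv": sd / mean})


class PairRatioTransformer(BaseEstimator, TransformerMixin):
    """Summarize a paired expression matrix into per-gene ratio statistics.

    ``fit`` computes the per-gene E_higher/E_lower ratio statistics over
    the selected pairs; ``transform`` returns them as a DataFrame
    (genes x [mean_ratio, sd_ratio, cv]).

    Parameters
    ----------
    eps:
        Pseudocount added to both values before forming the ratio.
    pairs:
        Optional subset of pair ids; default uses every complete pair.
    """

    def __init__(self, eps: float = 0.0, pairs: Sequence | None = None):
        self.eps = eps
        self.pairs = pairs

    def fit(self, X: PairedExpressionMatrix, y=None) -> "PairRatioTransformer":
        self.ratio_stats_ = ratio_table(X, pairs=self.pairs, eps=self.eps)
        self.n_pairs_ = len(self.pairs) if self.pairs is not None else len(X.pairs)
        return self

    def transform(self, X: PairedExpressionMatrix | None = None) -> pd.DataFrame:
        check_is_fitted(self, "ratio_stats_")
        if X is None:
            return self.ratio_stats_
        return ratio_table(X, pairs=self.pairs, eps=self.eps)

    def exceedance(self, cutoffs: Sequence[float] = (2, 5, 10)) -> dict[float, int]:
        check_is_fitted(self, "ratio_stats_")
        return count_exceedance(self.ratio_stats_, cutoffs)


def count_exceedance(
    stats: pd.DataFrame, cutoffs: Sequence[float] = (2, 5, 10)
) -> dict[float, int]:
    """Genes whose mean pair ratio strictly exceeds each cutoff.

    Counts are monotone non-increasing in the cutoff; e.g. the number of
    genes with an average within-pair imbalance >2, >5 and >10 fold.
    """
    mean = stats["mean_ratio"]
    return {float(c): int((mean > c).sum()) for c in cutoffs}


def rank_for_gsea(
    stats: pd.DataFrame, key: Literal["cv", "mean_ratio"] = "cv"
) -> pd.DataFrame:
    """Rank genes high-to-low for enrichment analysis.

    Primary key descending; ties broken by mean_ratio descending, then
    gene symbol ascending, giving a deterministic strict ordering.
    Returns a two-column frame (gene, score) suitable for single
    ranked-list tools.
    """
    if key not in ("cv", "mean_ratio"):
        raise ValueError("key must be 'cv' or 'mean_ratio'")
    df = stats.reset_index()
    df = df.rename(columns={df.columns[0]: "gene"})
    df = df.sort_values(
        by=[key, "mean_ratio", "gene"], ascending=[False, False, True], kind="mergesort"
    )
    return df[["gene", key]].rename(columns={key: "score"}).reset_index(drop=True)


def differential_expression(
    matrix: PairedExpressionMatrix,
    group_a: str,
    group_b: str,
    alpha: float = 0.05,
    variant: Literal["pooled", "welch"] = "pooled",
    adjust: bool = False,
) -> pd.DataFrame:
    """Per-gene two-sample t-test between two sample groups.

    Returns a DataFrame (gene x [t, p, zero_variance]) plus attributes
    ``.attrs['n_significant']`` and ``.attrs['frac_significant']`` for
    the raw p < alpha count.  Genes constant within both groups are
    flagged and assigned p = 1.  Benjamini-Hochberg q-values are added
    as column ``q`` when ``adjust`` is set.
    """
    if matrix.group is None:
        raise ValueError("matrix carries no group annotation")
    sa = matrix.samples_in_group(group_a)
    sb = matrix.samples_in_group(group_b)
    if len(sa) < 2 or len(sb) < 2:
        raise ValueError("need at least 2 samples per group")
    xa = matrix.values[sa].to_numpy(dtype=float)
    xb = matrix.values[sb].to_numpy(dtype=float)
    zero_var = (xa.std(axis=1) == 0) & (xb.std(axis=1) == 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        res = sps.ttest_ind(xa, xb, axis=1, equal_var=(variant == "pooled"))
    t = np.asarray(res.statistic, dtype=float)
    p = np.asarray(res.pvalue, dtype=float)
    t[zero_var] = 0.0
    p[zero_var] = 1.0
    out = pd.DataFrame({"t": t, "p": p, "zero_variance": zero_var}, index=matrix.genes)
    if adjust:
        out["q"] = sps.false_discovery_control(out["p"].to_numpy(), method="bh")
    n_sig = int((out["p"] < alpha).sum())
    out.attrs["n_significant"] = n_sig
    out.attrs["frac_significant"] = n_sig / len(out)
    out.attrs["alpha"] = alpha
    return out


def _two_means_split_1d(values: np.ndarray) -> np.ndarray:
    """Exact 1-D two-means: boolean mask of the high cluster.

    Scans every split of the sorted values and minimizes the within-
    cluster sum of squares; deterministic (first minimal split wins).
    """
    order = np.argsort(values, kind="mergesort")
    v = values[order]
    n = v.size
    best_cost, best_split = np.inf, None
    csum = np.concatenate([[0.0], np.cumsum(v)])
    csq = np.concatenate([[0.0], np.cumsum(v**2)])

    def sse(i, j):  # [i, j)
        s, q, m = csum[j] - csum[i], csq[j] - csq[i], j - i
        return q - s * s / m

    for split in range(1, n):
        cost = sse(0, split) + sse(split, n)
        if cost < best_cost - 1e-12:
            best_cost, best_split = cost, split
    high = np.zeros(n, dtype=bool)
    high[best_split:] = True
    mask = np.zeros(n, dtype=bool)
    mask[order] = high
    return mask


def call_sex_by_xist(
    matrix: PairedExpressionMatrix, gene: str = "Xist"
) -> pd.Series:
    """Call sample sex from Xist expression by a two-means split.

    Xist is expressed from the inactive X of females; samples in the low
    cluster are called male, the high cluster female.  Constant input is
    degenerate: all samples get one class with a warning.  The call is
    invariant to rescaling all values by a positive constant.
    """
    if gene not in matrix.genes:
        raise ValueError(f"gene {gene!r} not in matrix")
    x = matrix.values.loc[gene].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        warnings.warn(
            f"{gene} expression is constant; sex call degenerate, assigning one class",
            UserWarning,
            stacklevel=2,
        )
        return pd.Series("male", index=matrix.samples, name="sex")
    high = _two_means_split_1d(x)
    return pd.Series(np.where(high, "female", "male"), index=matrix.samples, name="sex")


def group_similarity(
    matrix: PairedExpressionMatrix, group_a: str, group_b: str
) -> float:
    """R^2 between the per-gene mean profiles of two sample groups.

    Squared Pearson correlation of the gene-wise group means, on the
    values as stored; identical groups give 1, independent random
    profiles approach 0.
    """
    sa = matrix.samples_in_group(group_a)
    sb = matrix.samples_in_group(group_b)
    ma = matrix.values[sa].mean(axis=1).to_numpy()
    mb = matrix.values[sb].mean(axis=1).to_numpy()
    if np.std(ma) == 0 or np.std(mb) == 0:
        raise ValueError("zero variance in a group mean profile")
    r = np.corrcoef(ma, mb)[0, 1]
    return float(r * r)
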