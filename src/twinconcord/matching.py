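"""Co-twin matching by class-discovery clustering.

Twin samples are clustered hierarchically on correlation distance; a
true pair whose two members merge directly as sibling leaves (a
"first-order connection" in a constellation map) counts as correctly
matched.  To interpret an observed match count k out of n pairs, the
exact null distribution of k under a uniformly random perfect matching
of the 2n samples is computed combinatorially: the expected number of
matched pairs by chance is n/(2n-1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .stats import ContingencyTable2x2, FisherResult, fisher_exact_2x2

__all__ = [
    "MatchReport",
    "CoTwinMatcher",
    "correlation_distance",
    "hierarchical_cluster",
    "count_first_order_matches",
    "count_mutual_nn_matches",
    "count_greedy_matches",
    "null_match_distribution",
    "compare_match_rates",
]


@dataclass(frozen=True)
class MatchReport:
    """Observed co-twin match count and its exact combinatorial null."""

    n_pairs: int
    k_matched: int
    linkage: str
    definition: str
    null_pmf: np.ndarray  # P(K = k), k = 0..n_pairs
    expected_k_null: float  # mean of null_pmf = n/(2n-1)
    p_ge_observed: float  # P(K >= k_matched) under the null

    def to_dict(self) -> dict:
        return {
            "n_pairs": self.n_pairs,
            "k_matched": self.k_matched,
            "linkage": self.linkage,
            "definition": self.definition,
            "expected_k_null": self.expected_k_null,
            "p_ge_observed": self.p_ge_observed,
            "null_pmf": self.null_pmf.tolist(),
        }


def correlation_distance(X: np.ndarray | pd.DataFrame) -> np.ndarray:
    """Pairwise distance d(i,j) = 1 - Pearson r between sample profiles.

    ``X`` is samples x genes.  Identical profiles have distance 0;
    perfectly anti-correlated profiles have distance 2.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D samples x genes array with >= 2 samples")
    sd = X.std(axis=1)
    if (sd == 0).any():
        bad = np.nonzero(sd == 0)[0].tolist()
        raise ValueError(f"constant sample profiles (no correlation defined): rows {bad}")
    d = 1.0 - np.corrcoef(X)
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    return np.clip(d, 0.0, 2.0)


def hierarchical_cluster(
    dist: np.ndarray, linkage: Literal["average", "complete", "single"] = "average"
) -> np.ndarray:
    """Agglomerative clustering of a square distance matrix.

    Returns the scipy linkage matrix (full binary merge tree; n-1 rows
    for n samples).  The merge order is deterministic for a given
    distance matrix.
    """
    dist = np.asarray(dist, dtype=float)
    if dist.ndim != 2 or dist.shape[0] != dist.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(dist, dist.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    if (np.diag(dist) != 0).any():
        raise ValueError("distance matrix must have a zero diagonal")
    condensed = squareform(dist, checks=False)
    return hierarchy.linkage(condensed, method=linkage)


def count_first_order_matches(
    Z: np.ndarray, pair_of_leaf: Sequence | Mapping[int, object]
) -> int:
    """Number of true pairs merged as sibling leaves in the dendrogram.

    A merge row joining two original leaves (both cluster ids < n) that
    belong to the same true pair counts as one first-order match.
    Invariant to leaf relabeling.
    """
    Z = np.asarray(Z)
    n = Z.shape[0] + 1
    if not isinstance(pair_of_leaf, Mapping):
        pair_of_leaf = dict(enumerate(pair_of_leaf))
    if set(pair_of_leaf.keys()) != set(range(n)):
        raise ValueError("pair_of_leaf must cover every leaf index 0..n-1")
    k = 0
    for i, j in Z[:, :2].astype(int):
        if i < n and j < n and pair_of_leaf[i] == pair_of_leaf[j]:
            k += 1
    return k


def count_greedy_matches(dist: np.ndarray, pair_of_leaf: Sequence) -> int:
    """Match count under greedy nearest-pair full matching.

    Repeatedly pairs the two closest unpaired samples until all are
    paired, then counts reproduced true pairs.  Unlike the sibling-leaf
    dendrogram count, this produces a full perfect matching, so under
    exchangeable (signal-free) samples its distribution is exactly the
    uniform-matching null of :func:`null_match_distribution`.
    """
    dist = np.asarray(dist, dtype=float)
    n = dist.shape[0]
    d = dist.copy()
    np.fill_diagonal(d, np.inf)
    labels = list(pair_of_leaf)
    unpaired = list(range(n))
    k = 0
    while len(unpaired) > 1:
        sub = d[np.ix_(unpaired, unpaired)]
        i, j = np.unravel_index(np.argmin(sub), sub.shape)  # first minimum: lowest index
        a, b = unpaired[i], unpaired[j]
        if labels[a] == labels[b]:
            k += 1
        unpaired = [u for u in unpaired if u not in (a, b)]
    return k


def count_mutual_nn_matches(dist: np.ndarray, pair_of_leaf: Sequence) -> int:
    """Alternative match definition: members are mutual nearest neighbours."""
    dist = np.asarray(dist, dtype=float)
    n = dist.shape[0]
    d = dist.copy()
    np.fill_diagonal(d, np.inf)
    nn = d.argmin(axis=1)
    labels = list(pair_of_leaf)
    matched_pairs = set()
    for i in range(n):
        j = nn[i]
        if nn[j] == i and labels[i] == labels[j]:
            matched_pairs.add(labels[i])
    return len(matched_pairs)


def _double_factorial_odd(m: int) -> int:
    """(2m-1)!! = number of perfect matchings of 2m items; 1 for m = 0."""
    out = 1
    for i in range(1, 2 * m, 2):
        out *= i
    return out


def null_match_distribution(n_pairs: int) -> np.ndarray:
    """Exact pmf of the number of true pairs reproduced by chance.

    2n samples are partitioned uniformly at random into n unordered
    pairs; K counts how many of the n original pairs are reproduced.
    By inclusion-exclusion, the number of matchings avoiding all
    original pairs among 2m items is D(m) = sum_j (-1)^j C(m,j)
    (2(m-j)-1)!!, and P(K=k) = C(n,k) D(n-k) / (2n-1)!!.  The mean is
    n/(2n-1) (each pair is matched with probability 1/(2n-1)).
    """
    n = int(n_pairs)
    if n < 1:
        raise ValueError("n_pairs must be >= 1")
    total = _double_factorial_odd(n)

    def avoiding(m: int) -> int:
        return sum(
            (-1) ** j * math.comb(m, j) * _double_factorial_odd(m - j) for j in range(m + 1)
        )

    pmf = np.array(
        [float(Fraction(math.comb(n, k) * avoiding(n - k), total)) for k in range(n + 1)]
    )
    return pmf


def compare_match_rates(k1: int, n1: int, k2: int, n2: int) -> FisherResult:
    """Two-sided Fisher exact test comparing two match rates k/n."""
    if not (0 <= k1 <= n1 and 0 <= k2 <= n2):
        raise ValueError("need 0 <= k <= n for both rates")
    return fisher_exact_2x2(ContingencyTable2x2(k1, n1 - k1, k2, n2 - k2))


class CoTwinMatcher(BaseEstimator):
    """Cluster paired samples and score co-twin recovery against chance.

    ``fit`` takes a samples x genes matrix ``X`` and per-sample pair
    labels ``y`` (each label on exactly two samples), clusters the
    samples hierarchically on correlation distance, counts the true
    pairs joined by a first-order (sibling-leaf) connection, and
    attaches the exact combinatorial null of that count.

    Parameters
    ----------
    linkage:
        ``average`` (default), ``complete`` or ``single``.
    definition:
        ``sibling`` (first-order dendrogram connection, default),
        ``mnn`` (mutual nearest neighbours on the distance matrix) or
        ``greedy`` (nearest-pair full matching; the definition whose
        chance distribution is exactly the combinatorial null).

    Attributes
    ----------
    distance_ : ndarray
        Correlation-distance matrix.
    linkage_matrix_ : ndarray
        scipy linkage matrix.
    n_pairs_, k_matched_ : int
    null_pmf_ : ndarray
        Exact pmf of the chance match count.
    expected_k_null_ : float
        n/(2n-1), the chance expectation.
    p_value_ : float
        P(K >= k_matched) under the null.
    report_ : MatchReport
    """

    def __init__(
        self,
        linkage: Literal["average", "complete", "single"] = "average",
        definition: Literal["sibling", "mnn"] = "sibling",
    ):
        self.linkage = linkage
        self.definition = definition

    def fit(self, X, y) -> "CoTwinMatcher":
        X = np.asarray(X, dtype=float)
        labels = np.asarray(y, dtype=object)
        if X.shape[0] != labels.shape[0]:
            raise ValueError("X rows and pair labels must align")
        uniq, counts = np.unique(labels, return_counts=True)
        if (counts != 2).any():
            bad = uniq[counts != 2].tolist()
            raise ValueError(f"each pair label must occur exactly twice: {bad}")
        self.distance_ = correlation_distance(X)
        self.linkage_matrix_ = hierarchical_cluster(self.distance_, self.linkage)
        if self.definition == "sibling":
            k = count_first_order_matches(self.linkage_matrix_, list(labels))
        elif self.definition == "mnn":
            k = count_mutual_nn_matches(self.distance_, list(labels))
        elif self.definition == "greedy":
            k = count_greedy_matches(self.distance_, list(labels))
        else:
            raise ValueError(f"unknown match definition: {self.definition!r}")
        n = len(uniq)
        pmf = null_match_distribution(n)
        self.n_pairs_ = n
        self.k_matched_ = int(k)
        self.null_pmf_ = pmf
        self.expected_k_null_ = float(np.arange(n + 1) @ pmf)
        self.p_value_ = float(pmf[self.k_matched_ :].sum())
        self.report_ = MatchReport(
            n_pairs=n,
            k_matched=self.k_matched_,
            linkage=self.linkage,
            definition=self.definition,
            null_pmf=pmf,
            expected_k_null=self.expected_k_null_,
            p_ge_observed=self.p_value_,
        )
        return self

    def fit_predict(self, X, y) -> int:
        """Fit and return the matched-pair count."""
        return self.fit(X, y).k_matched_

    def to_newick(self, leaf_names: Sequence[str] | None = None) -> str:
        """Export the fitted dendrogram in Newick format."""
        check_is_fitted(self, "linkage_matrix_")
        tree = hierarchy.to_tree(self.linkage_matrix_)
        n = self.linkage_matrix_.shape[0] + 1
        names = list(leaf_names) if leaf_names is not None else [f"s{i}" for i in range(n)]

        def walk(node, parent_dist):
            length = max(parent_dist - node.dist, 0.0)
            if node.is_leaf():
                return f"{names[node.id]}:{length:.6g}"
            left = walk(node.left, node.dist)
            right = walk(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        return walk(tree, tree.dist) + ";"
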