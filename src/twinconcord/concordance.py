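"""Lineage-count concordance of monozygotic (MZ) twin blastocysts.

A blastocyst allocates its cells to three founder lineages:
trophectoderm (TE, CDX2+), epiblast (EPI, NANOG+) and primitive endoderm
(pEnd, SOX17+).  Background variation is estimated from dizygotic (DZ)
pairs — unrelated embryos of the same mother paired at random — as the
median per-lineage absolute cell-count difference.  Because an MZ twin
blastocyst carries roughly half the cells of an intact embryo, half of
each DZ median is taken as the concordance threshold; an MZ pair whose
members differ by more than the threshold in any lineage is
"discordant", otherwise "concordant".  With DZ medians of 18/4/4 cells
this yields the 9-2-2 criterion.

All statistics here are invariant to swapping the two members of a pair,
which carry no intrinsic order.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

logger = logging.getLogger(__name__)

LINEAGES = ("te", "epi", "pend")
CONCORDANT = "concordant"
DISCORDANT = "discordant"

__all__ = [
    "LineageCounts",
    "TwinPairRecord",
    "ConcordanceThresholds",
    "ConcordanceClassifier",
    "derive_thresholds",
    "classify_pair",
    "concordance_summary",
    "lineage_correlation",
    "pairs_from_frame",
    "frame_from_pairs",
]


@dataclass(frozen=True)
class LineageCounts:
    """Cell counts of one blastocyst: TE, EPI and pEnd compartments."""

    te: int
    epi: int
    pend: int

    def __post_init__(self) -> None:
        for name in LINEAGES:
            v = getattr(self, name)
            if v < 0 or int(v) != v:
                raise ValueError(f"{name} count must be a non-negative integer, got {v!r}")

    @property
    def total(self) -> int:
        return self.te + self.epi + self.pend


@dataclass(frozen=True)
class TwinPairRecord:
    """One twin pair (MZ or DZ); members a/b are unordered labels."""

    pair_id: str
    zygosity: Literal["MZ", "DZ"]
    member_a: LineageCounts
    member_b: LineageCounts
    condition: str | None = None

    def __post_init__(self) -> None:
        if self.zygosity not in ("MZ", "DZ"):
            raise ValueError(f"zygosity must be 'MZ' or 'DZ', got {self.zygosity!r}")

    def abs_diff(self, lineage: str) -> int:
        return abs(getattr(self.member_a, lineage) - getattr(self.member_b, lineage))


@dataclass(frozen=True)
class ConcordanceThresholds:
    """Per-lineage maximum cell-count differences for concordance.

    Each value is half of the corresponding median DZ difference and is
    kept unrounded (halving an odd median gives a half-integer).
    """

    te_max: float
    epi_max: float
    pend_max: float

    def __post_init__(self) -> None:
        for name in ("te_max", "epi_max", "pend_max"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.te_max, self.epi_max, self.pend_max)


def derive_thresholds(dz_pairs: Sequence[TwinPairRecord]) -> ConcordanceThresholds:
    """Halve the median per-lineage absolute DZ differences.

    For each lineage the absolute within-pair cell-count difference is
    computed, its median taken across pairs (even counts give the mean of
    the central two) and halved; DZ medians of (18, 4, 4) yield the
    (9, 2, 2) thresholds.
    """
    dz_pairs = list(dz_pairs)
    if len(dz_pairs) < 2:
        raise ValueError("need at least 2 DZ pairs to estimate background variation")
    bad = [p.pair_id for p in dz_pairs if p.zygosity != "DZ"]
    if bad:
        raise ValueError(f"non-DZ records in threshold derivation: {bad}")
    halved = [float(np.median([p.abs_diff(lin) for p in dz_pairs])) / 2.0 for lin in LINEAGES]
    return ConcordanceThresholds(*halved)


def classify_pair(pair: TwinPairRecord, thresholds: ConcordanceThresholds) -> str:
    """Concordant iff every lineage difference is within its threshold.

    The rule is conjunctive: |dTE| <= te_max and |dEPI| <= epi_max and
    |dpEnd| <= pend_max; boundary equality counts as concordant.  Any
    single lineage strictly exceeding its limit makes the pair
    discordant.  Symmetric in the two members.
    """
    limits = thresholds.as_tuple()
    ok = all(pair.abs_diff(lin) <= lim for lin, lim in zip(LINEAGES, limits))
    return CONCORDANT if ok else DISCORDANT


class ConcordanceClassifier(BaseEstimator):
    """Classify MZ twin pairs as concordant/discordant against DZ background.

    ``fit`` derives the per-lineage thresholds from DZ pairs (half the
    median absolute difference); ``predict`` applies the conjunctive
    rule to MZ pairs.  Thresholds may instead be supplied directly via
    the ``thresholds`` parameter, in which case ``fit`` accepts ``None``.

    Parameters
    ----------
    thresholds:
        Optional pre-specified :class:`ConcordanceThresholds` (e.g. the
        9-2-2 criterion); bypasses derivation from DZ data.

    Attributes
    ----------
    thresholds_ : ConcordanceThresholds
        Fitted per-lineage limits.
    n_dz_pairs_ : int
        Number of DZ pairs used (0 when thresholds were supplied).
    """

    def __init__(self, thresholds: ConcordanceThresholds | None = None):
        self.thresholds = thresholds

    def fit(self, X: Sequence[TwinPairRecord] | None, y=None) -> "ConcordanceClassifier":
        if self.thresholds is not None:
            self.thresholds_ = self.thresholds
            self.n_dz_pairs_ = 0
        else:
            if X is None:
                raise ValueError("DZ pairs required when no thresholds are supplied")
            self.thresholds_ = derive_thresholds(list(X))
            self.n_dz_pairs_ = len(list(X))
        return self

    def predict(self, X: Sequence[TwinPairRecord]) -> np.ndarray:
        check_is_fitted(self, "thresholds_")
        return np.array([classify_pair(p, self.thresholds_) for p in X], dtype=object)

    def fit_predict(self, X, y=None, *, dz_pairs=None) -> np.ndarray:
        return self.fit(dz_pairs).predict(X)


def concordance_summary(
    mz_pairs: Sequence[TwinPairRecord],
    thresholds: ConcordanceThresholds,
    group_by_condition: bool = False,
    low_n: int = 5,
) -> pd.DataFrame:
    """Per-group concordant/discordant proportions with binomial SDs.

    Returns a table with columns ``group, n_pairs, n_concordant,
    prop_concordant, prop_discordant, sd, low_n``; ``sd`` is the
    binomial standard deviation sqrt(p(1-p)/n) of the proportion.
    Groups with no pairs are dropped with a logged warning; groups with
    fewer than ``low_n`` pairs are flagged.
    """
    mz_pairs = list(mz_pairs)
    if not mz_pairs:
        raise ValueError("no MZ pairs supplied")
    labels = [classify_pair(p, thresholds) for p in mz_pairs]
    if group_by_condition:
        keys = [p.condition if p.condition is not None else "(none)" for p in mz_pairs]
    else:
        keys = ["all"] * len(mz_pairs)
    df = pd.DataFrame({"group": keys, "label": labels})
    rows = []
    for group, sub in df.groupby("group", sort=True):
        n = len(sub)
        if n == 0:  # pragma: no cover - groupby never yields empty groups
            logger.warning("dropping empty group %r", group)
            continue
        k = int((sub["label"] == CONCORDANT).sum())
        p = k / n
        rows.append(
            {
                "group": group,
                "n_pairs": n,
                "n_concordant": k,
                "prop_concordant": p,
                "prop_discordant": 1.0 - p,
                "sd": float(np.sqrt(p * (1 - p) / n)),
                "low_n": n < low_n,
            }
        )
    return pd.DataFrame(rows)


def lineage_correlation(mz_pairs: Sequence[TwinPairRecord], lineage: str) -> float:
    """Member-order-invariant Pearson r of a lineage's counts across pairs.

    Because members are unordered, r is computed on the doubled set
    {(a_i, b_i)} U {(b_i, a_i)}, which symmetrizes the statistic.  A low
    EPI correlation relative to TE indicates that discordance is driven
    by the epiblast compartment.
    """
    if lineage not in LINEAGES:
        raise ValueError(f"lineage must be one of {LINEAGES}")
    mz_pairs = list(mz_pairs)
    if len(mz_pairs) < 2:
        raise ValueError("need at least 2 pairs")
    a = np.array([getattr(p.member_a, lineage) for p in mz_pairs], dtype=float)
    b = np.array([getattr(p.member_b, lineage) for p in mz_pairs], dtype=float)
    x = np.concatenate([a, b])
    y = np.concatenate([b, a])
    if np.std(x) == 0:
        raise ValueError(f"zero variance in {lineage} counts; correlation undefined")
    return float(np.corrcoef(x, y)[0, 1])


def pairs_from_frame(df: pd.DataFrame) -> list[TwinPairRecord]:
    """Build pair records from a long table.

    Expected columns: pair_id, zygosity, member (a/b), te, epi, pend and
    optionally condition; each pair_id must appear with exactly the two
    members a and b.
    """
    required = {"pair_id", "zygosity", "member", "te", "epi", "pend"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    records = []
    for pair_id, sub in df.groupby("pair_id", sort=True):
        if sorted(sub["member"]) != ["a", "b"]:
            raise ValueError(f"pair {pair_id!r} must have exactly members 'a' and 'b'")
        row_a = sub[sub["member"] == "a"].iloc[0]
        row_b = sub[sub["member"] == "b"].iloc[0]
        zyg = set(sub["zygosity"])
        if len(zyg) != 1:
            raise ValueError(f"pair {pair_id!r} has inconsistent zygosity")
        cond = None
        if "condition" in sub.columns:
            vals = sub["condition"].dropna().unique()
            cond = str(vals[0]) if len(vals) else None
        records.append(
            TwinPairRecord(
                pair_id=str(pair_id),
                zygosity=zyg.pop(),
                member_a=LineageCounts(int(row_a["te"]), int(row_a["epi"]), int(row_a["pend"])),
                member_b=LineageCounts(int(row_b["te"]), int(row_b["epi"]), int(row_b["pend"])),
                condition=cond,
            )
        )
    return records


def frame_from_pairs(pairs: Iterable[TwinPairRecord]) -> pd.DataFrame:
    """Inverse of :func:`pairs_from_frame` (long format, one row per member)."""
    rows = []
    for p in pairs:
        for member, counts in (("a", p.member_a), ("b", p.member_b)):
            rows.append(
                {
                    "pair_id": p.pair_id,
                    "zygosity": p.zygosity,
                    "member": member,
                    "te": counts.te,
                    "epi": counts.epi,
                    "pend": counts.pend,
                    "condition": p.condition,
                }
            )
    return pd.DataFrame(rows)
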