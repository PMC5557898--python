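"""Epiblast contribution of the two blastomere progenies.

In lineage-traced, non-bisected embryos each two-cell blastomere's
progeny carries a distinct fluorescent label; NANOG-positive epiblast
(EPI) nuclei are assigned to one progeny or the other.  The dominant
fraction — the larger EPI compartment over the total EPI count — ranges
from 0.5 (perfectly balanced contribution) to 1.0 (single-blastomere
origin) and classifies embryos as balanced (<= 0.6), intermediate
((0.6, 0.8]) or skewed (> 0.8).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

logger = logging.getLogger(__name__)

BALANCED = "balanced"
INTERMEDIATE = "intermediate"
SKEWED = "skewed"
CLASSES = (BALANCED, INTERMEDIATE, SKEWED)

__all__ = [
    "TracedBlastocyst",
    "dominant_fraction",
    "classify_contribution",
    "tracing_summary",
    "CLASSES",
]


@dataclass(frozen=True)
class TracedBlastocyst:
    """EPI cell counts of the two labeled blastomere progenies."""

    embryo_id: str
    epi_a: int  # NANOG+ nuclei in the green-labeled progeny
    epi_b: int  # NANOG+ nuclei in the orange/red-labeled progeny
    total_cells: int | None = None
    cohort: str | None = None  # e.g. "intact" or "twin"

    def __post_init__(self) -> None:
        if self.epi_a < 0 or self.epi_b < 0:
            raise ValueError("EPI counts must be non-negative")


def dominant_fraction(rec: TracedBlastocyst) -> float:
    """max(epi_a, epi_b) / (epi_a + epi_b); symmetric in the two labels.

    Always in [0.5, 1]; undefined (raises) when the embryo has no EPI
    cells — such records are excluded upstream.
    """
    total = rec.epi_a + rec.epi_b
    if total < 1:
        raise ValueError(f"embryo {rec.embryo_id!r} has zero EPI cells; fraction undefined")
    return max(rec.epi_a, rec.epi_b) / total


def classify_contribution(
    frac: float, balanced_max: float = 0.6, skewed_min: float = 0.8
) -> str:
    """Band a dominant fraction: balanced [0.5, 0.6], skewed (0.8, 1].

    The gap between the two named bands is an explicit ``intermediate``
    class ((0.6, 0.8] by default) rather than being silently merged;
    the upper balanced bound is closed and the skewed bound is open at
    0.8 (one blastomere supplying *more than* 80%).
    """
    if not 0.5 <= frac <= 1.0:
        raise ValueError(f"dominant fraction must lie in [0.5, 1], got {frac}")
    if frac <= balanced_max:
        return BALANCED
    if frac > skewed_min:
        return SKEWED
    return INTERMEDIATE


def tracing_summary(
    records: list[TracedBlastocyst],
    balanced_max: float = 0.6,
    skewed_min: float = 0.8,
) -> pd.DataFrame:
    """Class counts and fractions over traced embryos.

    Zero-EPI embryos are excluded from the fractions but reported on a
    QC row (class ``excluded_zero_epi``).  Class counts over included
    records sum to the included total.
    """
    counts = {c: 0 for c in CLASSES}
    excluded = 0
    for rec in records:
        if rec.epi_a + rec.epi_b < 1:
            excluded += 1
            continue
        counts[classify_contribution(dominant_fraction(rec), balanced_max, skewed_min)] += 1
    included = sum(counts.values())
    if excluded:
        logger.warning("excluded %d zero-EPI blastocyst(s) from tracing summary", excluded)
    rows = [
        {
            "class": c,
            "n": counts[c],
            "fraction": counts[c] / included if included else 0.0,
        }
        for c in CLASSES
    ]
    rows.append({"class": "excluded_zero_epi", "n": excluded, "fraction": float("nan")})
    return pd.DataFrame(rows)
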