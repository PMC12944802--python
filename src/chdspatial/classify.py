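"""Five-category local-association classification of areas.

Each area is labelled by the significance and sign pattern of its local
Lee coefficient: not significant (local pseudo-p above alpha), otherwise
High/Low for each variable by the sign of its lagged centred value. With x
the background population and y the disease population, "low_high" (low
background, high disease) is the epidemiologically interesting category —
proportionally more cases than people.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .lee import LocalLeeResult

logger = logging.getLogger(__name__)

#: The five categories. Signed categories are named x-call then y-call.
CATEGORIES = ("high_high", "high_low", "low_low", "low_high", "not_significant")

#: Grouping used in reports: concordant ("normal") vs discordant signed calls.
NORMAL = ("high_high", "low_low")
DISCORDANT = ("high_low", "low_high")


@dataclass
class AreaClassification:
    """Per-area category labels plus the alpha they were called at.

    ``table`` has columns area_id, category, pseudo_p; islands are listed
    separately and never classified.
    """

    table: pd.DataFrame
    alpha: float
    islands: list[str]


def round_half_away(value: float) -> int:
    """Round to the nearest integer, halves away from zero."""
    return int(math.copysign(math.floor(abs(value) + 0.5), value))


def classify_areas(local: LocalLeeResult, alpha: float = 0.05) -> AreaClassification:
    """Assign each non-island area one of the five categories.

    pseudo_p > alpha -> not_significant; otherwise the High/Low call for
    each variable is the sign of its lagged centred value (positive ->
    High; zero or negative -> Low, a deterministic tie-break that is
    logged when it fires).
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    island_set = set(local.islands)
    rows = []
    for i, aid in enumerate(local.area_ids):
        if aid in island_set:
            continue
        p = float(local.pseudo_p[i])
        if p > alpha:
            cat = "not_significant"
        else:
            lx = float(local.lag_x_centred[i])
            ly = float(local.lag_y_centred[i])
            if lx == 0 or ly == 0:
                logger.info("zero lagged centred value at %s treated as Low", aid)
            cat = ("high" if lx > 0 else "low") + "_" + ("high" if ly > 0 else "low")
        rows.append((aid, cat, p))
    table = pd.DataFrame(rows, columns=["area_id", "category", "pseudo_p"])
    return AreaClassification(table=table, alpha=alpha, islands=list(local.islands))


@dataclass
class CategorySummary:
    """Counts and integer percentages of classified areas per category."""

    counts: dict[str, int]  # all five categories
    grouped_counts: dict[str, int]  # not_significant / normal / discordant
    percentages: dict[str, int]  # five categories, integer percent
    grouped_percentages: dict[str, int]
    total: int


def percentages_from_counts(counts: dict[str, int]) -> dict[str, int]:
    """Integer percentages of a count table, halves rounded away from zero."""
    total = sum(counts.values())
    if total == 0:
        raise ValueError("empty count table")
    return {k: round_half_away(100.0 * v / total) for k, v in counts.items()}


def summarize_categories(classification: AreaClassification) -> CategorySummary:
    """Category counts, the normal/discordant grouping, and integer
    percentages of all classified areas."""
    if classification.table.empty:
        raise ValueError("empty classification")
    vc = classification.table["category"].value_counts()
    counts = {c: int(vc.get(c, 0)) for c in CATEGORIES}
    grouped = {
        "not_significant": counts["not_significant"],
        "normal": sum(counts[c] for c in NORMAL),
        "discordant": sum(counts[c] for c in DISCORDANT),
    }
    return CategorySummary(
        counts=counts,
        grouped_counts=grouped,
        percentages=percentages_from_counts(counts),
        grouped_percentages=percentages_from_counts(grouped),
        total=int(sum(counts.values())),
    )
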