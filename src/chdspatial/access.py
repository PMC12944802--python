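"""Remoteness assignment, hospital accessibility and report tables.

Maps per-area remoteness population shares to a single categorical label
(argmax share), classifies hospitals into the three service categories
(emergency department, >=200 beds, size-keyword description), derives the
three "within a 1-hour drive" boolean outcomes per area, and produces the
population-distribution and category cross-tabulation tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .classify import CATEGORIES, AreaClassification, round_half_away
from .cohort import AreaCounts
from .synthetic import REMOTENESS_LABELS, HospitalRecord

logger = logging.getLogger(__name__)

#: Hospital service categories, matching the three access flags.
HOSPITAL_CATEGORIES = ("ed", "200beds", "keyword")

ACCESS_FLAG_COLUMNS = {
    "ed": "within_60min_ed",
    "200beds": "within_60min_200beds",
    "keyword": "within_60min_keyword",
}

_SIZE_KEYWORDS = ("large", "major", "medium")

#: Populations reported in the distribution tables.
POPULATION_GROUPS = ("total", "chd", "complex_chd")


@dataclass
class AccessProfile:
    """Per-area remoteness label and the three hospital-proximity booleans.

    ``table`` is indexed by area_id with columns remoteness,
    within_60min_ed, within_60min_200beds, within_60min_keyword.
    """

    table: pd.DataFrame
    threshold_minutes: float


def assign_remoteness(shares) -> str:
    """Label an area by its largest remoteness population share.

    Ties break toward the less remote label (fixed order Major Cities >
    Inner Regional > Outer Regional > Remote > Very Remote).
    """
    s = np.asarray(shares, dtype=float)
    if s.shape != (5,):
        raise ValueError("expected five shares")
    if np.any(s < 0):
        raise ValueError("shares must be nonnegative")
    if abs(s.sum() - 1.0) > 1e-6:
        logger.warning("remoteness shares sum to %.6f, not 1", s.sum())
    return REMOTENESS_LABELS[int(np.argmax(s))]  # argmax takes the first max


def classify_hospital(h: HospitalRecord) -> tuple[bool, bool, bool]:
    """(is_ed, is_200beds, is_keyword) for one hospital.

    The bed cutoff is inclusive (>= 200); keyword matching is a
    case-insensitive substring test for "large", "major" or "medium".
    """
    desc = h.description.lower()
    return (
        bool(h.has_ed),
        h.beds >= 200,
        any(k in desc for k in _SIZE_KEYWORDS),
    )


def access_flags(
    travel: pd.DataFrame,
    hospitals: list[HospitalRecord],
    threshold_minutes: float = 60.0,
) -> pd.DataFrame:
    """Per-area booleans: is any hospital of each category within the
    drive-time threshold (minutes, inclusive)?

    ``travel`` is the complete area x hospital minutes matrix. A category
    with no hospitals yields all-False with a logged warning.
    """
    hosp_by_cat: dict[str, list[str]] = {c: [] for c in HOSPITAL_CATEGORIES}
    for h in hospitals:
        is_ed, is_beds, is_kw = classify_hospital(h)
        if is_ed:
            hosp_by_cat["ed"].append(h.hospital_id)
        if is_beds:
            hosp_by_cat["200beds"].append(h.hospital_id)
        if is_kw:
            hosp_by_cat["keyword"].append(h.hospital_id)
    missing = set(h.hospital_id for h in hospitals) - set(travel.columns)
    if missing:
        raise ValueError(f"travel matrix missing hospital column(s): {sorted(missing)}")
    out = pd.DataFrame(index=travel.index.copy())
    for cat, hids in hosp_by_cat.items():
        col = ACCESS_FLAG_COLUMNS[cat]
        if not hids:
            logger.warning("no hospitals in category %r; %s is False everywhere", cat, col)
            out[col] = False
        else:
            out[col] = (travel[hids].min(axis=1) <= threshold_minutes).to_numpy()
    return out


def build_access_profile(
    shares: pd.DataFrame,
    travel: pd.DataFrame,
    hospitals: list[HospitalRecord],
    threshold_minutes: float = 60.0,
) -> AccessProfile:
    """Remoteness labels plus the three access flags for every area."""
    remoteness = shares.apply(lambda row: assign_remoteness(row.to_numpy()), axis=1)
    flags = access_flags(travel, hospitals, threshold_minutes)
    table = flags.copy()
    table.insert(0, "remoteness", remoteness.reindex(table.index))
    return AccessProfile(table=table, threshold_minutes=threshold_minutes)


def distribution_by_group(counts: AreaCounts, profile: AccessProfile) -> pd.DataFrame:
    """Share of each population (total, disease, complex disease) living in
    each remoteness category and on each side of each access flag.

    Tidy output columns: grouping, level, population_group, count,
    proportion, percent (integer, halves away from zero).
    """
    t = counts.table.set_index("area_id")
    prof = profile.table
    if set(t.index) != set(prof.index):
        raise ValueError("counts and access profile cover different areas")
    prof = prof.reindex(t.index)
    pops = {
        "total": t["population"],
        "chd": t["chd_count"],
        "complex_chd": t["complex_chd_count"],
    }
    totals = {g: float(s.sum()) for g, s in pops.items()}
    if any(v == 0 for v in totals.values()):
        raise ValueError("zero national total; proportions undefined")
    rows = []
    groupings: list[tuple[str, pd.Series, list]] = [
        ("remoteness", prof["remoteness"], list(REMOTENESS_LABELS))
    ]
    for col in ACCESS_FLAG_COLUMNS.values():
        groupings.append((col, prof[col], [True, False]))
    for gname, key, levels in groupings:
        for level in levels:
            in_level = key == level
            for pg, series in pops.items():
                c = float(series[in_level.to_numpy()].sum())
                prop = c / totals[pg]
                rows.append((gname, str(level), pg, int(c), prop, round_half_away(100 * prop)))
    return pd.DataFrame(
        rows, columns=["grouping", "level", "population_group", "count", "proportion", "percent"]
    )


def crosstab_categories(
    classification: AreaClassification, profile: AccessProfile
) -> pd.DataFrame:
    """Area counts of each local-correlation category per remoteness label
    and per access flag, tidy: grouping, level, category, n_areas.

    Marginals over levels reproduce the classification's category counts.
    """
    cls = classification.table.set_index("area_id")
    missing = set(cls.index) - set(profile.table.index)
    if missing:
        raise ValueError(f"classified area(s) missing from access profile: {sorted(missing)[:5]}")
    prof = profile.table.reindex(cls.index)
    rows = []
    groupings: list[tuple[str, pd.Series, list]] = [
        ("remoteness", prof["remoteness"], list(REMOTENESS_LABELS))
    ]
    for col in ACCESS_FLAG_COLUMNS.values():
        groupings.append((col, prof[col], [True, False]))
    for gname, key, levels in groupings:
        for level in levels:
            sub = cls.loc[(key == level).to_numpy(), "category"]
            vc = sub.value_counts()
            for cat in CATEGORIES:
                rows.append((gname, str(level), cat, int(vc.get(cat, 0))))
    return pd.DataFrame(rows, columns=["grouping", "level", "category", "n_areas"])
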