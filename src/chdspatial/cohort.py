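"""Cohort filters and per-area aggregation.

Applies the registry inclusion criteria (structural disease only, still
living), locates each individual's point in the area geography, and
aggregates to per-area counts of the disease population and its complex
(moderate-or-severe) subset — the two count variables the spatial
correlation compares against the background population.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Point

from .synthetic import AreaSet, PersonRecord

logger = logging.getLogger(__name__)

#: Severity labels counted as complex disease. "unknown" is deliberately
#: excluded: it contributes to the total count only.
COMPLEX_SEVERITIES = ("moderate", "severe")


@dataclass
class ExclusionTally:
    """Records removed per criterion, in application order."""

    non_structural: int
    deceased: int


@dataclass
class AreaCounts:
    """Per-area population and disease counts.

    ``table`` columns: area_id, population, chd_count, complex_chd_count;
    every area is present even at zero counts. ``unlocated`` tallies
    filtered records whose point fell outside every polygon (geocoding
    failures).
    """

    table: pd.DataFrame
    unlocated: int

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(population, chd_count, complex_chd_count) aligned to table order."""
        t = self.table
        return (
            t["population"].to_numpy(float),
            t["chd_count"].to_numpy(float),
            t["complex_chd_count"].to_numpy(float),
        )


def filter_cohort(records: list[PersonRecord]) -> tuple[list[PersonRecord], ExclusionTally]:
    """Retain alive individuals with structural disease.

    Criteria apply in order: non-structural records are removed first, then
    deceased records among the remainder, and the tally reports each step's
    removals. Idempotent.
    """
    structural = [r for r in records if r.structural_chd]
    n_non_structural = len(records) - len(structural)
    kept = [r for r in structural if r.alive]
    n_deceased = len(structural) - len(kept)
    return kept, ExclusionTally(non_structural=n_non_structural, deceased=n_deceased)


class AreaLocator:
    """Point-in-polygon lookup against an AreaSet.

    Containment is boundary-inclusive; a point on a shared edge is assigned
    to the first containing area in area_id order (a deterministic
    tie-break). Points outside every polygon return None.
    """

    def __init__(self, areas: AreaSet):
        self.areas = areas
        self._tree = shapely.STRtree(np.asarray(areas.polygons, dtype=object))
        order = np.argsort(np.asarray(areas.area_ids, dtype=object))
        self._rank = np.empty(len(areas), dtype=int)
        self._rank[order] = np.arange(len(areas))

    def locate(self, point: tuple[float, float]) -> str | None:
        hits = self._tree.query(Point(point), predicate="covered_by")
        if len(hits) == 0:
            return None
        best = min(hits, key=lambda j: self._rank[j])
        return self.areas.area_ids[int(best)]

    def locate_many(self, points: np.ndarray) -> list[str | None]:
        """Vectorised lookup for an (m, 2) array of points."""
        pts = shapely.points(points)
        pi, gi = self._tree.query(pts, predicate="covered_by")
        best: dict[int, int] = {}
        for p, g in zip(pi.tolist(), gi.tolist()):
            if p not in best or self._rank[g] < self._rank[best[p]]:
                best[p] = g
        return [
            self.areas.area_ids[best[m]] if m in best else None for m in range(len(points))
        ]


def locate_point(point: tuple[float, float], areas: AreaSet) -> str | None:
    """Locate one point; builds a throwaway index (use AreaLocator in loops)."""
    return AreaLocator(areas).locate(point)


def aggregate_counts(
    records: list[PersonRecord],
    areas: AreaSet,
    populations: dict[str, int],
) -> AreaCounts:
    """Aggregate filtered records to per-area counts.

    ``chd_count`` counts located records; ``complex_chd_count`` the subset
    with moderate or severe disease. Records outside every polygon are
    excluded and tallied as unlocated. The populations table must cover
    exactly the area set.
    """
    unknown = set(populations) - set(areas.area_ids)
    if unknown:
        raise ValueError(f"unknown area_id(s) in populations table: {sorted(unknown)[:5]}")
    missing = set(areas.area_ids) - set(populations)
    if missing:
        raise ValueError(f"populations table missing area(s): {sorted(missing)[:5]}")

    chd = {a: 0 for a in areas.area_ids}
    cplx = {a: 0 for a in areas.area_ids}
    unlocated = 0
    if records:
        locator = AreaLocator(areas)
        pts = np.array([r.point for r in records], dtype=float)
        assigned = locator.locate_many(pts)
        for rec, aid in zip(records, assigned):
            if aid is None:
                unlocated += 1
                continue
            chd[aid] += 1
            if rec.severity in COMPLEX_SEVERITIES:
                cplx[aid] += 1
    if unlocated:
        logger.info("%d record(s) outside every polygon (geocoding failures)", unlocated)
    table = pd.DataFrame(
        {
            "area_id": areas.area_ids,
            "population": [populations[a] for a in areas.area_ids],
            "chd_count": [chd[a] for a in areas.area_ids],
            "complex_chd_count": [cplx[a] for a in areas.area_ids],
        }
    )
    return AreaCounts(table=table, unlocated=unlocated)
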