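"""Synthetic study-input generator.

Emulates the inputs of a national small-area disease-mapping study of
congenital heart disease (CHD): a polygonal geography of census-style areas
(~10,000 inhabitants each), per-area population counts, individual disease
records with point locations and demographic attributes, hospitals with
attributes, an area-by-hospital travel-time matrix, and per-area remoteness
population shares.

The generator is the ground-truth machine for the analysis pipeline: a
relative-risk surface with optional injected contiguous clusters defines
where the disease population departs from the background population, so
recovery and calibration of the spatial statistics can be tested without
any external data.

All samplers are deterministic under a fixed integer seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Point, Polygon, box

logger = logging.getLogger(__name__)

#: Severity labels, in the order attribute-mix probabilities are given.
SEVERITY_LABELS = ("mild", "moderate", "severe", "unknown")

#: Sex labels, in the order attribute-mix probabilities are given.
SEX_LABELS = ("female", "male", "other_unknown")

#: Birth-decade labels, least to most recent.
DECADE_LABELS = ("<1980", "1980-1989", "1990-1999", "2000-2009", "2010-2019", "2020-2024")

#: Remoteness category labels, least to most remote. Index order matters:
#: argmax ties are broken toward the less remote label.
REMOTENESS_LABELS = ("Major Cities", "Inner Regional", "Outer Regional", "Remote", "Very Remote")

#: Default attribute mix: severity shares (mild, moderate, severe, unknown),
#: sex shares (female, male, other/unknown) and birth-decade shares, matching
#: the registry cohort's marginal distributions.
DEFAULT_ATTRIBUTE_MIX = {
    "severity": (0.31, 0.38, 0.17, 0.13),
    "sex": (0.46, 0.48, 0.06),
    "birth_decade": (0.09, 0.13, 0.22, 0.24, 0.26, 0.07),
}

HOSPITAL_DESCRIPTIONS = (
    "Major Referral Hospital",
    "Large District Hospital",
    "Medium Regional Hospital",
    "Community Health Clinic",
    "Rural Nursing Post",
    "Day Procedure Centre",
)

DEFAULT_BED_SIZES = (20, 60, 120, 250, 600)
DEFAULT_BED_PROBS = (0.30, 0.25, 0.20, 0.15, 0.10)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class AreaSet:
    """A set of planar polygonal areas with unique string identifiers.

    Stands in for the census statistical areas (SA2) of the real study.
    ``lattice_shape`` is populated for generated rectangular lattices and,
    together with ``torus``, enables exact wrap-around adjacency used in
    identity tests.
    """

    area_ids: list[str]
    polygons: list[Polygon]
    torus: bool = False
    lattice_shape: tuple[int, int] | None = None  # (nx, ny), row-major ids
    cell_size: float | None = None

    def __post_init__(self) -> None:
        if len(self.area_ids) != len(self.polygons):
            raise ValueError("area_ids and polygons must have equal length")
        if len(set(self.area_ids)) != len(self.area_ids):
            raise ValueError("area_ids must be unique")
        if self.torus and self.lattice_shape is None:
            raise ValueError("torus topology requires a lattice_shape")

    def __len__(self) -> int:
        return len(self.area_ids)

    @property
    def index(self) -> dict[str, int]:
        return {a: i for i, a in enumerate(self.area_ids)}

    def centroids(self) -> np.ndarray:
        """(n, 2) array of polygon centroids, in area order."""
        pts = shapely.centroid(np.asarray(self.polygons, dtype=object))
        return shapely.get_coordinates(pts)


@dataclass
class RiskSurface:
    """Per-area multiplicative relative risk, 1.0 = baseline."""

    relative_risk: dict[str, float]
    cluster_ids: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if any(r <= 0 for r in self.relative_risk.values()):
            raise ValueError("relative risks must be positive")

    def as_array(self, area_ids: list[str]) -> np.ndarray:
        return np.array([self.relative_risk[a] for a in area_ids], dtype=float)


@dataclass
class PersonRecord:
    """One registry individual: a geocoded point plus the flags and
    attributes the cohort filters and severity grouping use."""

    person_id: str
    point: tuple[float, float]
    alive: bool
    structural_chd: bool
    severity: str
    sex: str
    birth_decade: str

    def __post_init__(self) -> None:
        if self.severity not in SEVERITY_LABELS:
            raise ValueError(f"unknown severity {self.severity!r}")
        if self.sex not in SEX_LABELS:
            raise ValueError(f"unknown sex {self.sex!r}")


@dataclass
class HospitalRecord:
    hospital_id: str
    has_ed: bool
    beds: int
    description: str

    def __post_init__(self) -> None:
        if self.beds < 0:
            raise ValueError("beds must be nonnegative")


# ---------------------------------------------------------------------------
# Geography
# ---------------------------------------------------------------------------


def make_lattice(nx: int, ny: int, cell_size: float = 1.0, torus: bool = False) -> AreaSet:
    """Build an ``nx`` x ``ny`` lattice of square areas.

    Area identifiers are row-major ("A0000" for the south-west cell). The
    torus flag is recorded so that contiguity construction can wrap edges,
    which makes the spatial-lag operator doubly stochastic — useful for
    exact algebraic identities.
    """
    if nx < 1 or ny < 1:
        raise ValueError("lattice dimensions must be positive")
    if cell_size <= 0:
        raise ValueError("cell_size must be positive")
    width = max(4, len(str(nx * ny - 1)))
    ids, polys = [], []
    for iy in range(ny):
        for ix in range(nx):
            ids.append(f"A{iy * nx + ix:0{width}d}")
            polys.append(
                box(ix * cell_size, iy * cell_size, (ix + 1) * cell_size, (iy + 1) * cell_size)
            )
    return AreaSet(ids, polys, torus=torus, lattice_shape=(nx, ny), cell_size=cell_size)


# ---------------------------------------------------------------------------
# Populations and risk
# ---------------------------------------------------------------------------


def sample_area_populations(
    areas: AreaSet,
    mean_pop: float = 10_000.0,
    dispersion: float = 0.35,
    seed: int = 0,
) -> dict[str, int]:
    """Draw per-area population counts from a log-normal distribution.

    ``mean_pop`` is the arithmetic mean of the distribution (census areas
    are designed around ~10,000 inhabitants); ``dispersion`` is the standard
    deviation of log population, giving the right skew of real census area
    sizes. Counts are rounded and floored at 1.
    """
    if mean_pop <= 0 or dispersion <= 0:
        raise ValueError("mean_pop and dispersion must be positive")
    rng = np.random.default_rng(seed)
    mu = np.log(mean_pop) - 0.5 * dispersion**2  # arithmetic mean = mean_pop
    draws = rng.lognormal(mean=mu, sigma=dispersion, size=len(areas))
    pops = np.maximum(1, np.rint(draws)).astype(int)
    return dict(zip(areas.area_ids, (int(p) for p in pops)))


def inject_clusters(
    areas: AreaSet,
    n_clusters: int,
    cluster_radius: int,
    relative_risk: float,
    seed: int = 0,
    max_tries: int = 1000,
) -> RiskSurface:
    """Plant ``n_clusters`` disjoint contiguous elevated-risk blocks.

    Each block is a seed area plus all areas within rook-contiguity graph
    distance ``cluster_radius``; block areas get ``relative_risk``, all
    others 1.0. Raises if disjoint blocks cannot be placed.
    """
    if n_clusters < 0 or cluster_radius < 0:
        raise ValueError("n_clusters and cluster_radius must be nonnegative")
    if relative_risk <= 0:
        raise ValueError("relative_risk must be positive")
    if n_clusters > len(areas):
        raise ValueError("more clusters than areas")

    rr = {a: 1.0 for a in areas.area_ids}
    if n_clusters == 0:
        return RiskSurface(rr, set())

    from .weights import contiguity_neighbors  # deferred: avoids cycle at import

    adjacency = contiguity_neighbors(areas, rule="rook")
    rng = np.random.default_rng(seed)
    n = len(areas)

    def ball(center: int) -> set[int]:
        seen = {center}
        frontier = {center}
        for _ in range(cluster_radius):
            frontier = {j for i in frontier for j in adjacency[i]} - seen
            seen |= frontier
        return seen

    for _ in range(max_tries):
        seeds = rng.choice(n, size=n_clusters, replace=False)
        blocks = [ball(int(s)) for s in seeds]
        union: set[int] = set()
        ok = True
        for b in blocks:
            if union & b:
                ok = False
                break
            union |= b
        if ok:
            cluster_ids = {areas.area_ids[i] for i in union}
            for a in cluster_ids:
                rr[a] = relative_risk
            return RiskSurface(rr, cluster_ids)
    raise ValueError(
        f"could not place {n_clusters} disjoint clusters of radius {cluster_radius} "
        f"in {n} areas after {max_tries} tries"
    )


def sample_area_case_counts(
    populations: dict[str, int],
    risk: RiskSurface,
    base_prevalence: float,
    seed: int = 0,
) -> dict[str, int]:
    """Per-area disease counts: Binomial(population, prevalence x RR)."""
    if base_prevalence < 0:
        raise ValueError("base_prevalence must be nonnegative")
    max_rr = max(risk.relative_risk[a] for a in populations) if populations else 1.0
    if base_prevalence * max_rr >= 1:
        raise ValueError("base_prevalence x relative_risk must be < 1")
    rng = np.random.default_rng(seed)
    out = {}
    for a, pop in populations.items():
        out[a] = int(rng.binomial(pop, base_prevalence * risk.relative_risk[a]))
    return out


# ---------------------------------------------------------------------------
# Individuals
# ---------------------------------------------------------------------------


def _sample_points_in_polygon(poly: Polygon, k: int, rng: np.random.Generator) -> np.ndarray:
    """k points uniform in the interior of ``poly`` by rejection sampling."""
    if k == 0:
        return np.empty((0, 2))
    minx, miny, maxx, maxy = poly.bounds
    pts: list[np.ndarray] = []
    need = k
    while need > 0:
        m = max(16, 2 * need)
        xs = rng.uniform(minx, maxx, m)
        ys = rng.uniform(miny, maxy, m)
        inside = shapely.contains_xy(poly, xs, ys)  # strict interior
        got = np.column_stack([xs[inside], ys[inside]])[:need]
        if len(got):
            pts.append(got)
            need -= len(got)
    return np.concatenate(pts)


def _sample_labels(rng, labels, probs, size):
    p = np.asarray(probs, dtype=float)
    p = p / p.sum()
    return rng.choice(len(labels), size=size, p=p)


def sample_chd_individuals(
    areas: AreaSet,
    populations: dict[str, int],
    risk: RiskSurface,
    base_prevalence: float = 0.009,
    attribute_mix: dict | None = None,
    seed: int = 0,
    nonstructural_frac: float = 0.05,
    deceased_frac: float = 0.05,
) -> list[PersonRecord]:
    """Generate individual disease records.

    Per-area case counts follow Binomial(population, prevalence x RR); each
    case is placed uniformly inside its area's polygon, with severity, sex
    and birth decade drawn from ``attribute_mix``. On top of the alive,
    structural cases, two contamination fractions add records that the
    cohort filters must remove: non-structural diagnoses and deceased
    individuals. The number of alive structural records per area therefore
    equals the binomial case count exactly.
    """
    if not 0 <= nonstructural_frac < 1 or not 0 <= deceased_frac < 1:
        raise ValueError("contamination fractions must be in [0, 1)")
    mix = dict(DEFAULT_ATTRIBUTE_MIX)
    if attribute_mix:
        mix.update(attribute_mix)

    rng = np.random.default_rng(seed)
    counts = sample_area_case_counts(
        populations, risk, base_prevalence, seed=int(rng.integers(2**31))
    )
    n_cases = sum(counts.values())

    # (area_index, alive, structural) rows; contamination spread uniformly.
    rows: list[tuple[int, bool, bool]] = []
    for a, c in counts.items():
        rows.extend((areas.index[a], True, True) for _ in range(c))
    n_ns = int(rng.binomial(n_cases, nonstructural_frac)) if n_cases else 0
    n_dead = int(rng.binomial(n_cases, deceased_frac)) if n_cases else 0
    extra_areas = rng.integers(0, len(areas), size=n_ns + n_dead)
    for j in range(n_ns):
        rows.append((int(extra_areas[j]), True, False))
    for j in range(n_dead):
        rows.append((int(extra_areas[n_ns + j]), False, True))

    total = len(rows)
    if total == 0:
        return []
    sev = _sample_labels(rng, SEVERITY_LABELS, mix["severity"], total)
    sex = _sample_labels(rng, SEX_LABELS, mix["sex"], total)
    dec = _sample_labels(rng, DECADE_LABELS, mix["birth_decade"], total)

    # Group by area for vectorised point placement.
    by_area: dict[int, list[int]] = {}
    for r, (ai, _, _) in enumerate(rows):
        by_area.setdefault(ai, []).append(r)
    points = np.empty((total, 2))
    for ai, ridx in sorted(by_area.items()):
        points[ridx] = _sample_points_in_polygon(areas.polygons[ai], len(ridx), rng)

    records = []
    for r, (ai, alive, structural) in enumerate(rows):
        records.append(
            PersonRecord(
                person_id=f"P{r:06d}",
                point=(float(points[r, 0]), float(points[r, 1])),
                alive=alive,
                structural_chd=structural,
                severity=SEVERITY_LABELS[sev[r]],
                sex=SEX_LABELS[sex[r]],
                birth_decade=DECADE_LABELS[dec[r]],
            )
        )
    return records


# ---------------------------------------------------------------------------
# Hospitals, travel times, remoteness
# ---------------------------------------------------------------------------


def place_hospitals(
    areas: AreaSet,
    n_hospitals: int,
    seed: int = 0,
    ed_prob: float = 0.6,
    bed_sizes: tuple[int, ...] = DEFAULT_BED_SIZES,
    bed_probs: tuple[float, ...] = DEFAULT_BED_PROBS,
) -> tuple[list[HospitalRecord], dict[str, tuple[float, float]]]:
    """Place hospitals at uniformly chosen area centroids.

    Emergency-department status is Bernoulli(``ed_prob``); bed counts come
    from the discrete distribution (``bed_sizes``, ``bed_probs``);
    descriptions are drawn from a fixed word list that both contains and
    lacks the size keywords ("Large", "Major", "Medium") so the keyword
    classifier is exercised in both directions.
    """
    if n_hospitals < 1:
        raise ValueError("n_hospitals must be >= 1")
    rng = np.random.default_rng(seed)
    replace = n_hospitals > len(areas)
    cells = rng.choice(len(areas), size=n_hospitals, replace=replace)
    cents = areas.centroids()
    records, locations = [], {}
    for h in range(n_hospitals):
        hid = f"H{h:03d}"
        records.append(
            HospitalRecord(
                hospital_id=hid,
                has_ed=bool(rng.random() < ed_prob),
                beds=int(rng.choice(bed_sizes, p=np.asarray(bed_probs) / np.sum(bed_probs))),
                description=str(HOSPITAL_DESCRIPTIONS[rng.integers(len(HOSPITAL_DESCRIPTIONS))]),
            )
        )
        locations[hid] = (float(cents[cells[h], 0]), float(cents[cells[h], 1]))
    return records, locations


def compute_travel_times(
    areas: AreaSet,
    hospital_locations: dict[str, tuple[float, float]],
    speed: float,
) -> pd.DataFrame:
    """Straight-line travel-time matrix in minutes.

    ``speed`` is in coordinate length-units per hour; minutes =
    distance / speed * 60. Rows are areas, columns hospitals; the matrix is
    complete by construction.
    """
    if speed <= 0:
        raise ValueError("speed must be positive")
    if not hospital_locations:
        raise ValueError("at least one hospital required")
    cents = areas.centroids()
    hids = list(hospital_locations)
    hxy = np.array([hospital_locations[h] for h in hids], dtype=float)
    dist = np.hypot(
        cents[:, None, 0] - hxy[None, :, 0], cents[:, None, 1] - hxy[None, :, 1]
    )
    minutes = dist / speed * 60.0
    return pd.DataFrame(minutes, index=pd.Index(areas.area_ids, name="area_id"), columns=hids)


def assign_remoteness_shares(
    areas: AreaSet,
    city_centres: list[tuple[float, float]],
    band_radii: tuple[float, float, float, float],
    bleed: float = 0.2,
) -> pd.DataFrame:
    """Per-area population shares across the five remoteness categories.

    The distance from an area's centroid to the nearest city centre selects
    a band (four increasing radii cut five bands, least to most remote).
    The band receives 1 - ``bleed`` of the share; the rest bleeds equally
    into adjacent bands, so that argmax assignment is exercised on
    non-degenerate share vectors. ``bleed`` < 0.5 keeps the argmax at the
    centroid's own band.
    """
    radii = np.asarray(band_radii, dtype=float)
    if len(radii) != 4 or not np.all(np.diff(radii) > 0):
        raise ValueError("band_radii must be four strictly increasing values")
    if not 0 <= bleed < 0.5:
        raise ValueError("bleed must be in [0, 0.5)")
    if not city_centres:
        raise ValueError("at least one city centre required")
    cents = areas.centroids()
    cxy = np.asarray(city_centres, dtype=float)
    d = np.min(
        np.hypot(cents[:, None, 0] - cxy[None, :, 0], cents[:, None, 1] - cxy[None, :, 1]),
        axis=1,
    )
    bands = np.searchsorted(radii, d, side="right")  # 0..4
    shares = np.zeros((len(areas), 5))
    for i, b in enumerate(bands):
        nbrs = [bb for bb in (b - 1, b + 1) if 0 <= bb <= 4]
        if bleed and nbrs:
            shares[i, b] = 1.0 - bleed
            for bb in nbrs:
                shares[i, bb] = bleed / len(nbrs)
        else:
            shares[i, b] = 1.0
    return pd.DataFrame(
        shares, index=pd.Index(areas.area_ids, name="area_id"), columns=list(REMOTENESS_LABELS)
    )
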