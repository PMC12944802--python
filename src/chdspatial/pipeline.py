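"""Configuration, file formats and the end-to-end analysis driver.

The driver chains the stages of the study: simulate (or load) geography
and registry inputs -> cohort filters -> per-area aggregation -> contiguity
weights -> global and local Lee's L with Monte Carlo inference -> the
five-category classification -> remoteness / hospital-accessibility
profiles -> report tables. Every artifact is written as GeoJSON (RFC 7946)
or CSV (UTF-8, header row), and every run echoes its fully-resolved
configuration and seed so identical configurations reproduce byte-identical
outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from shapely.geometry import Polygon

from . import access as access_mod
from . import classify as classify_mod
from . import cohort as cohort_mod
from . import lee as lee_mod
from . import synthetic as synth
from . import weights as weights_mod
from .synthetic import REMOTENESS_LABELS, AreaSet, HospitalRecord, PersonRecord, RiskSurface

logger = logging.getLogger(__name__)


class SchemaError(ValueError):
    """An input file does not match its documented schema."""


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Fully-resolved parameters of one end-to-end run.

    Defaults describe the study conditions of the synthetic scenarios:
    census-style areas of ~10,000 inhabitants (log-normal, sigma of log
    0.35), disease prevalence 9 per 1,000, queen contiguity, 10,000
    Monte Carlo permutations, alpha 0.05 and a 60-minute drive threshold.
    """

    scenario: str = "null"
    nx: int = 20
    ny: int = 20
    cell_size: float = 1.0
    torus: bool = False
    mean_pop: float = 10_000.0
    dispersion: float = 0.35
    prevalence: float = 0.009
    n_clusters: int = 0
    cluster_radius: int = 2
    relative_risk: float = 3.0
    nonstructural_frac: float = 0.05
    deceased_frac: float = 0.05
    n_hospitals: int = 12
    speed: float = 12.0  # length units per hour
    city_centres: list = field(default_factory=lambda: [[0.0, 0.0]])
    band_radii: list = field(default_factory=lambda: [5.0, 10.0, 15.0, 20.0])
    bleed: float = 0.2
    weights_rule: str = "queen"
    R: int = 10_000
    alpha: float = 0.05
    threshold_minutes: float = 60.0
    seed: int = 0
    outdir: str = "chdspatial_run"

    def validate(self) -> None:
        if self.weights_rule not in ("queen", "rook"):
            raise ValueError("weights_rule must be 'queen' or 'rook'")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.R < 1:
            raise ValueError("R must be >= 1")
        if self.nx < 1 or self.ny < 1:
            raise ValueError("lattice dimensions must be positive")
        if not 0 <= self.prevalence < 1:
            raise ValueError("prevalence must be in [0, 1)")

    @classmethod
    def preset(cls, name: str, **overrides) -> "RunConfig":
        """Named scenario presets.

        "null": 20x20 lattice, no injected clusters (exchangeable counts).
        "clustered": same lattice with one radius-2 relative-risk-3 cluster.
        """
        if name not in PRESETS:
            raise ValueError(f"unknown scenario {name!r}; presets: {sorted(PRESETS)}")
        params = dict(PRESETS[name])
        params.update(overrides)
        cfg = cls(scenario=name, **params)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise SchemaError(f"unknown config key(s) in {path}: {sorted(unknown)}")
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


PRESETS: dict[str, dict] = {
    "null": {"n_clusters": 0},
    "clustered": {"n_clusters": 1, "cluster_radius": 2, "relative_risk": 3.0},
}

#: Stage names -> fixed substream indices, so e.g. changing R leaves the
#: synthetic data untouched.
_STAGE_STREAMS = {
    "populations": 0,
    "clusters": 1,
    "individuals": 2,
    "hospitals": 3,
    "global_test": 4,
    "local_test": 5,
}


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the one global seed."""
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=(_STAGE_STREAMS[stage],))
    return int(ss.generate_state(1, dtype=np.uint32)[0])


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def write_areas_geojson(areas: AreaSet, path: str | Path) -> None:
    features = []
    for aid, poly in zip(areas.area_ids, areas.polygons):
        features.append(
            {
                "type": "Feature",
                "properties": {"area_id": aid},
                "geometry": {
                    "type": "Polygon",
                    "coordinates": [[list(c) for c in poly.exterior.coords]],
                },
            }
        )
    doc = {
        "type": "FeatureCollection",
        "features": features,
        "lattice": {
            "torus": areas.torus,
            "shape": list(areas.lattice_shape) if areas.lattice_shape else None,
            "cell_size": areas.cell_size,
        },
    }
    Path(path).write_text(json.dumps(doc), encoding="utf-8")


def read_areas_geojson(path: str | Path) -> AreaSet:
    doc = json.loads(Path(path).read_text(encoding="utf-8"))
    if doc.get("type") != "FeatureCollection":
        raise SchemaError(f"{path}: not a GeoJSON FeatureCollection")
    ids, polys = [], []
    for k, feat in enumerate(doc.get("features", [])):
        props = feat.get("properties") or {}
        if "area_id" not in props:
            raise SchemaError(f"{path}: feature {k} missing 'area_id' property")
        geom = feat.get("geometry") or {}
        if geom.get("type") != "Polygon":
            raise SchemaError(f"{path}: feature {k} is not a Polygon")
        rings = geom["coordinates"]
        ids.append(str(props["area_id"]))
        polys.append(Polygon(rings[0], holes=rings[1:] or None))
    lat = doc.get("lattice") or {}
    shape = lat.get("shape")
    return AreaSet(
        ids,
        polys,
        torus=bool(lat.get("torus", False)),
        lattice_shape=tuple(shape) if shape else None,
        cell_size=lat.get("cell_size"),
    )


def _require_columns(df: pd.DataFrame, cols: list[str], path) -> None:
    for c in cols:
        if c not in df.columns:
            raise SchemaError(f"{path}: missing required column '{c}'")


def _read_csv(path: str | Path, cols: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, cols, path)
    return df


_BOOL = {"true": True, "false": False}


def _parse_bool(series: pd.Series, path, col) -> pd.Series:
    s = series.astype(str).str.lower()
    bad = ~s.isin(_BOOL)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise SchemaError(f"{path}: column '{col}' row {row}: not a boolean")
    return s.map(_BOOL)


def write_persons_csv(records: list[PersonRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "person_id": [r.person_id for r in records],
            "x": [r.point[0] for r in records],
            "y": [r.point[1] for r in records],
            "alive": [str(r.alive).lower() for r in records],
            "structural_chd": [str(r.structural_chd).lower() for r in records],
            "severity": [r.severity for r in records],
            "sex": [r.sex for r in records],
            "birth_decade": [r.birth_decade for r in records],
        }
    )
    df.to_csv(path, index=False, float_format="%.17g")


def read_persons_csv(path: str | Path) -> list[PersonRecord]:
    cols = ["person_id", "x", "y", "alive", "structural_chd", "severity", "sex", "birth_decade"]
    df = _read_csv(path, cols)
    alive = _parse_bool(df["alive"], path, "alive")
    structural = _parse_bool(df["structural_chd"], path, "structural_chd")
    return [
        PersonRecord(
            person_id=str(r.person_id),
            point=(float(r.x), float(r.y)),
            alive=bool(a),
            structural_chd=bool(s),
            severity=str(r.severity),
            sex=str(r.sex),
            birth_decade=str(r.birth_decade),
        )
        for r, a, s in zip(df.itertuples(index=False), alive, structural)
    ]


def write_hospitals_csv(
    hospitals: list[HospitalRecord], locations: dict[str, tuple[float, float]], path
) -> None:
    df = pd.DataFrame(
        {
            "hospital_id": [h.hospital_id for h in hospitals],
            "x": [locations[h.hospital_id][0] for h in hospitals],
            "y": [locations[h.hospital_id][1] for h in hospitals],
            "has_ed": [str(h.has_ed).lower() for h in hospitals],
            "beds": [h.beds for h in hospitals],
            "description": [h.description for h in hospitals],
        }
    )
    df.to_csv(path, index=False, float_format="%.17g")


def read_hospitals_csv(path) -> tuple[list[HospitalRecord], dict[str, tuple[float, float]]]:
    df = _read_csv(path, ["hospital_id", "x", "y", "has_ed", "beds", "description"])
    has_ed = _parse_bool(df["has_ed"], path, "has_ed")
    hospitals, locations = [], {}
    for r, ed in zip(df.itertuples(index=False), has_ed):
        hospitals.append(
            HospitalRecord(
                hospital_id=str(r.hospital_id),
                has_ed=bool(ed),
                beds=int(r.beds),
                description=str(r.description),
            )
        )
        locations[str(r.hospital_id)] = (float(r.x), float(r.y))
    return hospitals, locations


def write_populations_csv(populations: dict[str, int], path) -> None:
    pd.DataFrame(
        {"area_id": list(populations), "population": list(populations.values())}
    ).to_csv(path, index=False)


def read_populations_csv(path) -> dict[str, int]:
    df = _read_csv(path, ["area_id", "population"])
    return {str(a): int(p) for a, p in zip(df["area_id"], df["population"])}


def write_travel_csv(travel: pd.DataFrame, path) -> None:
    long = travel.stack().rename("minutes").reset_index()
    long.columns = ["area_id", "hospital_id", "minutes"]
    long.to_csv(path, index=False)


def read_travel_csv(path) -> pd.DataFrame:
    df = _read_csv(path, ["area_id", "hospital_id", "minutes"])
    wide = df.pivot(index="area_id", columns="hospital_id", values="minutes")
    if wide.isna().any().any():
        a = wide.index[wide.isna().any(axis=1)][0]
        raise SchemaError(f"{path}: travel matrix incomplete (e.g. area '{a}')")
    wide.index.name = "area_id"
    wide.columns.name = None
    return wide


def write_remoteness_csv(shares: pd.DataFrame, path) -> None:
    shares.reset_index().to_csv(path, index=False)


def read_remoteness_csv(path) -> pd.DataFrame:
    df = _read_csv(path, ["area_id", *REMOTENESS_LABELS])
    return df.set_index("area_id")[list(REMOTENESS_LABELS)].astype(float)


def write_area_counts_csv(counts: cohort_mod.AreaCounts, path) -> None:
    counts.table.to_csv(path, index=False)


def read_area_counts_csv(path) -> cohort_mod.AreaCounts:
    df = _read_csv(path, ["area_id", "population", "chd_count", "complex_chd_count"])
    return cohort_mod.AreaCounts(table=df, unlocated=0)


def write_weights_edges_csv(W: weights_mod.WeightsMatrix, path) -> None:
    rows = []
    for i, (nb, w) in enumerate(zip(W.neighbors, W.weights)):
        for j, wij in zip(nb.tolist(), w.tolist()):
            rows.append((W.area_ids[i], W.area_ids[j], wij))
    pd.DataFrame(rows, columns=["area_i", "area_j", "weight"]).to_csv(path, index=False)


def write_local_results_csv(local: lee_mod.LocalLeeResult, path) -> None:
    pd.DataFrame(
        {
            "area_id": local.area_ids,
            "local_L": local.local_l,
            "pseudo_p": local.pseudo_p,
            "lag_x_centred": local.lag_x_centred,
            "lag_y_centred": local.lag_y_centred,
        }
    ).to_csv(path, index=False)


def read_local_results_csv(path) -> lee_mod.LocalLeeResult:
    df = _read_csv(path, ["area_id", "local_L", "pseudo_p", "lag_x_centred", "lag_y_centred"])
    islands = [str(a) for a, p in zip(df["area_id"], df["pseudo_p"]) if pd.isna(p)]
    return lee_mod.LocalLeeResult(
        area_ids=[str(a) for a in df["area_id"]],
        local_l=df["local_L"].to_numpy(float),
        pseudo_p=df["pseudo_p"].to_numpy(float),
        lag_x_centred=df["lag_x_centred"].to_numpy(float),
        lag_y_centred=df["lag_y_centred"].to_numpy(float),
        n_permutations=0,
        alternative="two-sided",
        seed=0,
        islands=islands,
    )


def write_global_summary_csv(result: lee_mod.LeeResult, path) -> None:
    pd.DataFrame(
        [
            {
                "L": result.L,
                "sss_x": result.sss_x,
                "sss_y": result.sss_y,
                "lag_pearson": result.lag_pearson,
                "pseudo_p": result.pseudo_p,
                "R": result.n_permutations,
                "alternative": result.alternative,
                "seed": result.seed,
                "n": result.n,
            }
        ]
    ).to_csv(path, index=False)


def write_classification_csv(cls: classify_mod.AreaClassification, path) -> None:
    cls.table.to_csv(path, index=False)


def write_classification_geojson(
    cls: classify_mod.AreaClassification, areas: AreaSet, path
) -> None:
    """The map-attribute layer: polygons with their category property."""
    cat = dict(zip(cls.table["area_id"], cls.table["category"]))
    features = []
    for aid, poly in zip(areas.area_ids, areas.polygons):
        features.append(
            {
                "type": "Feature",
                "properties": {"area_id": aid, "category": cat.get(aid, "island")},
                "geometry": {
                    "type": "Polygon",
                    "coordinates": [[list(c) for c in poly.exterior.coords]],
                },
            }
        )
    Path(path).write_text(
        json.dumps({"type": "FeatureCollection", "features": features}), encoding="utf-8"
    )


def write_category_summary_csv(summary: classify_mod.CategorySummary, path) -> None:
    rows = [
        ("category", c, summary.counts[c], summary.percentages[c])
        for c in classify_mod.CATEGORIES
    ] + [
        ("group", g, summary.grouped_counts[g], summary.grouped_percentages[g])
        for g in ("not_significant", "normal", "discordant")
    ]
    pd.DataFrame(rows, columns=["kind", "label", "n_areas", "percent"]).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Driver
# ---------------------------------------------------------------------------


@dataclass
class RunResult:
    """In-memory handles to everything an end-to-end run produced."""

    config: RunConfig
    areas: AreaSet
    populations: dict[str, int]
    risk: RiskSurface
    records: list[PersonRecord]
    tally: cohort_mod.ExclusionTally
    counts: cohort_mod.AreaCounts
    W: weights_mod.WeightsMatrix
    global_result: lee_mod.LeeResult
    local_result: lee_mod.LocalLeeResult
    classification: classify_mod.AreaClassification
    summary: classify_mod.CategorySummary
    profile: access_mod.AccessProfile
    distributions: pd.DataFrame
    crosstabs: pd.DataFrame
    outdir: Path


def _stage(name: str):
    """Label any stage failure with the stage that raised it."""

    class _ctx:
        def __enter__(self):
            logger.info("stage: %s", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc
            return False

    return _ctx()


def run_pipeline(config: RunConfig, write: bool = True) -> RunResult:
    """Execute the full analysis for one configuration.

    Simulates the scenario's inputs, applies the cohort filters, aggregates
    to per-area counts, builds contiguity weights, computes global and
    local Lee's L with Monte Carlo pseudo-p-values, classifies areas,
    derives remoteness/accessibility profiles, and writes every artifact
    plus the echoed config and a run log into ``config.outdir``.
    """
    config.validate()
    outdir = Path(config.outdir)
    if write:
        outdir.mkdir(parents=True, exist_ok=True)

    with _stage("simulate"):
        areas = synth.make_lattice(config.nx, config.ny, config.cell_size, config.torus)
        populations = synth.sample_area_populations(
            areas, config.mean_pop, config.dispersion, seed=stage_seed(config.seed, "populations")
        )
        risk = synth.inject_clusters(
            areas,
            config.n_clusters,
            config.cluster_radius,
            config.relative_risk,
            seed=stage_seed(config.seed, "clusters"),
        )
        records = synth.sample_chd_individuals(
            areas,
            populations,
            risk,
            base_prevalence=config.prevalence,
            seed=stage_seed(config.seed, "individuals"),
            nonstructural_frac=config.nonstructural_frac,
            deceased_frac=config.deceased_frac,
        )
        hospitals, locations = synth.place_hospitals(
            areas, config.n_hospitals, seed=stage_seed(config.seed, "hospitals")
        )
        travel = synth.compute_travel_times(areas, locations, config.speed)
        shares = synth.assign_remoteness_shares(
            areas,
            [tuple(c) for c in config.city_centres],
            tuple(config.band_radii),
            bleed=config.bleed,
        )

    with _stage("filter"):
        kept, tally = cohort_mod.filter_cohort(records)

    with _stage("aggregate"):
        counts = cohort_mod.aggregate_counts(kept, areas, populations)

    with _stage("weights"):
        W = weights_mod.build_weights(areas, rule=config.weights_rule)

    pop_arr, chd_arr, _ = counts.arrays()
    with _stage("lee_global"):
        global_result = lee_mod.global_lee_analysis(
            W, pop_arr, chd_arr, R=config.R, seed=stage_seed(config.seed, "global_test")
        )
    with _stage("lee_local"):
        local_result = lee_mod.local_lee_analysis(
            W, pop_arr, chd_arr, R=config.R, seed=stage_seed(config.seed, "local_test")
        )

    with _stage("classify"):
        classification = classify_mod.classify_areas(local_result, alpha=config.alpha)
        summary = classify_mod.summarize_categories(classification)

    with _stage("access"):
        profile = access_mod.build_access_profile(
            shares, travel, hospitals, config.threshold_minutes
        )
        distributions = access_mod.distribution_by_group(counts, profile)
        crosstabs = access_mod.crosstab_categories(classification, profile)

    if write:
        with _stage("write"):
            config.to_yaml(outdir / "config.yaml")
            write_areas_geojson(areas, outdir / "areas.geojson")
            write_populations_csv(populations, outdir / "populations.csv")
            write_persons_csv(records, outdir / "persons.csv")
            write_hospitals_csv(hospitals, locations, outdir / "hospitals.csv")
            write_travel_csv(travel, outdir / "travel_times.csv")
            write_remoteness_csv(shares, outdir / "remoteness_shares.csv")
            write_area_counts_csv(counts, outdir / "area_counts.csv")
            write_weights_edges_csv(W, outdir / "weights_edges.csv")
            write_global_summary_csv(global_result, outdir / "global_summary.csv")
            write_local_results_csv(local_result, outdir / "local_results.csv")
            write_classification_csv(classification, outdir / "classification.csv")
            write_classification_geojson(classification, areas, outdir / "classification.geojson")
            write_category_summary_csv(summary, outdir / "category_summary.csv")
            distributions.to_csv(outdir / "distributions.csv", index=False)
            crosstabs.to_csv(outdir / "crosstabs.csv", index=False)
            _write_run_log(outdir / "run_log.txt", config, tally, counts, global_result)

    return RunResult(
        config=config,
        areas=areas,
        populations=populations,
        risk=risk,
        records=records,
        tally=tally,
        counts=counts,
        W=W,
        global_result=global_result,
        local_result=local_result,
        classification=classification,
        summary=summary,
        profile=profile,
        distributions=distributions,
        crosstabs=crosstabs,
        outdir=outdir,
    )


def _write_run_log(path, config, tally, counts, global_result) -> None:
    import chdspatial

    lines = [
        f"chdspatial {chdspatial.__version__}",
        f"python {sys.version.split()[0]} numpy {np.__version__} pandas {pd.__version__}",
        f"scenario={config.scenario} seed={config.seed} R={config.R} "
        f"rule={config.weights_rule} alpha={config.alpha}",
        f"excluded: non_structural={tally.non_structural} deceased={tally.deceased}",
        f"unlocated={counts.unlocated}",
        f"L={global_result.L:.6f} sss_x={global_result.sss_x:.6f} "
        f"sss_y={global_result.sss_y:.6f} lag_pearson={global_result.lag_pearson:.6f} "
        f"pseudo_p={global_result.pseudo_p:.6g}",
    ]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
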