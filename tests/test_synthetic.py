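"""Synthetic-geography generator: geometry, sampling distributions,
determinism and conservation."""

import numpy as np
import pytest
import shapely
from scipy import stats

import chdspatial as cs


class TestLattice:
    def test_single_cell_is_unit_square_with_no_neighbours(self):
        areas = cs.make_lattice(1, 1, 1.0)
        assert len(areas) == 1
        assert areas.polygons[0].equals(shapely.box(0, 0, 1, 1))
        W = cs.build_weights(areas)
        assert W.islands == areas.area_ids

    def test_3x3_centre_has_four_rook_neighbours(self, grid3):
        adj = cs.contiguity_neighbors(grid3, rule="rook")
        assert len(adj[4]) == 4

    def test_study_scale_lattice_area_count(self):
        # 1,872 + 427 + 151 classified areas in the study = 2,450
        areas = cs.make_lattice(50, 49)
        assert len(areas) == 2450
        assert len(set(areas.area_ids)) == 2450

    @pytest.mark.parametrize("nx,ny", [(0, 3), (3, 0), (-1, 2)])
    def test_nonpositive_dimensions_rejected(self, nx, ny):
        with pytest.raises(ValueError):
            cs.make_lattice(nx, ny)

    def test_polygons_interior_disjoint_and_simple(self):
        areas = cs.make_lattice(4, 3)
        for i, a in enumerate(areas.polygons):
            assert a.is_valid and a.is_simple
            for b in areas.polygons[i + 1 :]:
                assert a.intersection(b).area == 0.0


class TestPopulations:
    def test_mean_near_design_target_at_study_scale(self):
        areas = cs.make_lattice(50, 49)
        pops = cs.sample_area_populations(areas, mean_pop=10_000, seed=7)
        m = np.mean(list(pops.values()))
        assert abs(m - 10_000) / 10_000 < 0.05

    def test_small_dispersion_concentrates_at_mean(self):
        areas = cs.make_lattice(5, 5)
        pops = cs.sample_area_populations(areas, mean_pop=5000, dispersion=1e-4, seed=0)
        assert all(abs(p - 5000) <= 5 for p in pops.values())

    def test_determinism_and_positivity(self):
        areas = cs.make_lattice(6, 6)
        a = cs.sample_area_populations(areas, seed=3)
        b = cs.sample_area_populations(areas, seed=3)
        assert a == b
        assert min(a.values()) >= 1

    def test_invalid_parameters_rejected(self):
        areas = cs.make_lattice(2, 2)
        with pytest.raises(ValueError):
            cs.sample_area_populations(areas, mean_pop=-1)
        with pytest.raises(ValueError):
            cs.sample_area_populations(areas, dispersion=0)


class TestRiskSurface:
    def test_zero_clusters_gives_uniform_baseline(self):
        areas = cs.make_lattice(4, 4)
        risk = cs.inject_clusters(areas, 0, 2, 3.0, seed=0)
        assert set(risk.relative_risk.values()) == {1.0}
        assert risk.cluster_ids == set()

    def test_radius_one_cluster_is_rook_cross(self):
        areas = cs.make_lattice(5, 5)
        risk = cs.inject_clusters(areas, 1, 1, 3.0, seed=1)
        elevated = {a for a, r in risk.relative_risk.items() if r == 3.0}
        assert elevated == risk.cluster_ids
        # seed cell plus rook neighbours: 3 (corner), 4 (edge) or 5 cells
        assert len(elevated) in (3, 4, 5)
        # contiguity: elevated block is connected under rook adjacency
        adj = cs.contiguity_neighbors(areas, rule="rook")
        idx = {areas.index[a] for a in elevated}
        seen = {next(iter(idx))}
        frontier = set(seen)
        while frontier:
            frontier = {j for i in frontier for j in adj[i]} & idx - seen
            seen |= frontier
        assert seen == idx

    def test_determinism(self):
        areas = cs.make_lattice(6, 6)
        a = cs.inject_clusters(areas, 2, 1, 2.0, seed=9)
        b = cs.inject_clusters(areas, 2, 1, 2.0, seed=9)
        assert a.relative_risk == b.relative_risk and a.cluster_ids == b.cluster_ids

    def test_impossible_configuration_rejected(self):
        areas = cs.make_lattice(3, 3)
        with pytest.raises(ValueError):
            cs.inject_clusters(areas, 10, 1, 2.0, seed=0)  # more clusters than areas
        with pytest.raises(ValueError):
            cs.inject_clusters(areas, 4, 2, 2.0, seed=0, max_tries=50)  # cannot be disjoint


class TestCaseCounts:
    def test_zero_prevalence_zero_cases(self):
        areas = cs.make_lattice(3, 3)
        pops = {a: 1000 for a in areas.area_ids}
        risk = cs.RiskSurface({a: 1.0 for a in areas.area_ids})
        counts = cs.sample_area_case_counts(pops, risk, 0.0, seed=0)
        assert set(counts.values()) == {0}

    def test_mean_count_matches_binomial_expectation(self):
        # 400 areas of exactly 10,000 people at prevalence 0.009: the mean
        # per-area count should sit within 3 standard errors of n*p = 90.
        areas = cs.make_lattice(20, 20)
        pops = {a: 10_000 for a in areas.area_ids}
        risk = cs.RiskSurface({a: 1.0 for a in areas.area_ids})
        counts = cs.sample_area_case_counts(pops, risk, 0.009, seed=11)
        se = np.sqrt(10_000 * 0.009 * 0.991 / 400)
        assert abs(np.mean(list(counts.values())) - 90.0) < 3 * se

    def test_risk_multiplies_expectation(self):
        areas = cs.make_lattice(20, 20)
        pops = {a: 10_000 for a in areas.area_ids}
        rr = {a: (3.0 if i < 200 else 1.0) for i, a in enumerate(areas.area_ids)}
        counts = cs.sample_area_case_counts(pops, cs.RiskSurface(rr), 0.009, seed=5)
        hi = np.mean([counts[a] for a in areas.area_ids[:200]])
        lo = np.mean([counts[a] for a in areas.area_ids[200:]])
        assert 2.5 < hi / lo < 3.5

    def test_prevalence_times_risk_must_stay_below_one(self):
        areas = cs.make_lattice(2, 2)
        pops = {a: 100 for a in areas.area_ids}
        risk = cs.RiskSurface({a: 30.0 for a in areas.area_ids})
        with pytest.raises(ValueError):
            cs.sample_area_case_counts(pops, risk, 0.05, seed=0)

    def test_null_counts_exchangeable_across_areas(self):
        # With RR = 1 everywhere and equal populations, no area should be
        # systematically different: one-way ANOVA across areas over
        # repeated generations should not reject at alpha = 0.01.
        areas = cs.make_lattice(5, 5)
        pops = {a: 10_000 for a in areas.area_ids}
        risk = cs.RiskSurface({a: 1.0 for a in areas.area_ids})
        reps = np.array(
            [
                [cs.sample_area_case_counts(pops, risk, 0.009, seed=1000 + r)[a] for a in areas.area_ids]
                for r in range(120)
            ],
            dtype=float,
        )
        _, p = stats.f_oneway(*[reps[:, j] for j in range(reps.shape[1])])
        assert p > 0.01


@pytest.fixture(scope="module")
def generated():
    areas = cs.make_lattice(6, 6)
    pops = cs.sample_area_populations(areas, seed=2)
    risk = cs.RiskSurface({a: 1.0 for a in areas.area_ids})
    records = cs.sample_chd_individuals(areas, pops, risk, seed=21)
    return areas, pops, risk, records


class TestIndividuals:
    def test_zero_prevalence_empty_cohort(self):
        areas = cs.make_lattice(2, 2)
        pops = {a: 1000 for a in areas.area_ids}
        risk = cs.RiskSurface({a: 1.0 for a in areas.area_ids})
        assert cs.sample_chd_individuals(areas, pops, risk, base_prevalence=0.0, seed=0) == []

    def test_conservation_against_count_sampler(self, generated):
        # Alive structural records must reproduce the binomial case counts
        # that seed the generator, area by area in total.
        areas, pops, risk, records = generated
        alive_structural = [r for r in records if r.alive and r.structural_chd]
        expected_total = np.sum(
            [pops[a] for a in areas.area_ids]
        ) * 0.009  # sanity scale only
        assert len(alive_structural) == pytest.approx(expected_total, rel=0.2)
        counts = cs.aggregate_counts(alive_structural, areas, pops)
        assert counts.table["chd_count"].sum() + counts.unlocated == len(alive_structural)

    def test_severity_shares_match_attribute_mix(self, generated):
        _, _, _, records = generated
        sev = np.array([r.severity for r in records])
        n = len(sev)
        for label, p in zip(cs.SEVERITY_LABELS, (0.31, 0.38, 0.17, 0.13)):
            share = np.mean(sev == label)
            assert abs(share - p) < 4 * np.sqrt(p * (1 - p) / n)

    def test_every_point_inside_exactly_one_polygon(self, generated):
        areas, _, _, records = generated
        pts = shapely.points(np.array([r.point for r in records]))
        inside = np.zeros(len(records), dtype=int)
        for poly in areas.polygons:
            inside += shapely.contains(poly, pts).astype(int)
        assert np.all(inside == 1)

    def test_contamination_fractions_produce_filter_fodder(self, generated):
        _, _, _, records = generated
        n_ns = sum(not r.structural_chd for r in records)
        n_dead = sum(r.structural_chd and not r.alive for r in records)
        assert n_ns > 0 and n_dead > 0

    def test_determinism(self):
        areas = cs.make_lattice(3, 3)
        pops = {a: 2000 for a in areas.area_ids}
        risk = cs.RiskSurface({a: 1.0 for a in areas.area_ids})
        a = cs.sample_chd_individuals(areas, pops, risk, seed=4)
        b = cs.sample_chd_individuals(areas, pops, risk, seed=4)
        assert a == b


class TestHospitalsAndTravel:
    def test_single_hospital(self):
        areas = cs.make_lattice(3, 3)
        hospitals, locations = cs.place_hospitals(areas, 1, seed=0)
        assert len(hospitals) == 1 and hospitals[0].hospital_id in locations

    def test_descriptions_cover_keyword_and_non_keyword(self):
        areas = cs.make_lattice(10, 10)
        hospitals, _ = cs.place_hospitals(areas, 40, seed=3)
        kw = [cs.classify_hospital(h)[2] for h in hospitals]
        assert any(kw) and not all(kw)

    def test_determinism(self):
        areas = cs.make_lattice(4, 4)
        a = cs.place_hospitals(areas, 5, seed=8)
        b = cs.place_hospitals(areas, 5, seed=8)
        assert a == b

    def test_travel_time_zero_at_own_centroid(self):
        areas = cs.make_lattice(2, 1)
        travel = cs.compute_travel_times(areas, {"H0": (0.5, 0.5)}, speed=1.0)
        assert travel.loc["A0000", "H0"] == 0.0

    def test_two_cell_hand_calculation(self):
        # unit cells, hospital at the left centroid, speed 1 unit/hour:
        # the right area's centroid is 1 unit away -> 60 minutes.
        areas = cs.make_lattice(2, 1)
        travel = cs.compute_travel_times(areas, {"H0": (0.5, 0.5)}, speed=1.0)
        assert travel.loc["A0001", "H0"] == pytest.approx(60.0)

    def test_doubling_speed_halves_times(self):
        areas = cs.make_lattice(3, 3)
        _, locations = cs.place_hospitals(areas, 3, seed=1)
        t1 = cs.compute_travel_times(areas, locations, speed=5.0)
        t2 = cs.compute_travel_times(areas, locations, speed=10.0)
        np.testing.assert_allclose(t2.to_numpy(), t1.to_numpy() / 2)

    def test_empty_hospital_list_rejected(self):
        areas = cs.make_lattice(2, 2)
        with pytest.raises(ValueError):
            cs.compute_travel_times(areas, {}, speed=1.0)


class TestRemotenessShares:
    def test_city_centre_with_zero_bleed_is_pure_major_cities(self):
        areas = cs.make_lattice(1, 1)
        shares = cs.assign_remoteness_shares(areas, [(0.5, 0.5)], (1, 2, 3, 4), bleed=0.0)
        np.testing.assert_allclose(shares.iloc[0].to_numpy(), [1, 0, 0, 0, 0])

    def test_shares_sum_to_one(self):
        areas = cs.make_lattice(10, 10)
        shares = cs.assign_remoteness_shares(areas, [(0.0, 0.0)], (3, 6, 9, 12), bleed=0.2)
        np.testing.assert_allclose(shares.sum(axis=1).to_numpy(), 1.0, atol=1e-12)

    def test_bleed_preserves_argmax_band_exhaustively(self):
        areas = cs.make_lattice(10, 10)
        radii = (3.0, 6.0, 9.0, 12.0)
        shares = cs.assign_remoteness_shares(areas, [(0.0, 0.0)], radii, bleed=0.2)
        cents = areas.centroids()
        d = np.hypot(cents[:, 0], cents[:, 1])
        bands = np.searchsorted(np.array(radii), d, side="right")
        assert list(shares.to_numpy().argmax(axis=1)) == list(bands)

    def test_non_increasing_radii_rejected(self):
        areas = cs.make_lattice(2, 2)
        with pytest.raises(ValueError):
            cs.assign_remoteness_shares(areas, [(0, 0)], (3, 2, 9, 12))
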