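"""E2SFCA core: zone assignment, supply ratios, accessibility, hex grids."""

import math

import numpy as np
import pytest
from shapely.geometry import Point, box

from fca_access.demography import unit_centroid
from fca_access.errors import ConfigError
from fca_access.model import (
    Group,
    PopulationUnit,
    Service,
    ServiceSite,
    TravelZoneScheme,
)
from fca_access.e2sfca import (
    accessibility_at,
    compute_zone_sets,
    hex_grid,
    hex_tiling,
    normalize,
    supply_ratio,
    surface,
    zone_of,
    zones_of_points,
)
from fca_access.synthetic import ScenarioConfig, gen_road_network, gen_scenario
from fca_access.travel import catchment_zones

from conftest import (
    brute_force_accessibility,
    brute_force_ratios,
    lattice_instance,
    time_matrix,
)


def concentric_zones(scheme, radii=(100.0, 200.0, 300.0)):
    """Hand-built zone set: concentric squares centered at the origin."""
    from fca_access.model import CatchmentZoneSet
    hulls = [box(-r, -r, r, r) for r in radii]
    rings = [hulls[0]] + [o.difference(i) for i, o in zip(hulls, hulls[1:])]
    return CatchmentZoneSet(site_id="s", hulls=hulls, rings=rings, scheme=scheme)


def unit_at(xy, pop, uid="u1", group=Group.AGE15_64):
    return PopulationUnit(unit_id=uid, geometry=Point(xy), counts={group: pop})


def site_at(xy, sid="s", capacity=1.0):
    return ServiceSite(site_id=sid, x=xy[0], y=xy[1],
                       services=frozenset({Service.TESTING}), capacity=capacity)


class TestZoneOf:
    def test_inside_first_ring(self, scheme):
        assert zone_of(Point(0, 0), concentric_zones(scheme)) == 1

    def test_outside_outer_hull_is_none(self, scheme):
        assert zone_of(Point(500, 0), concentric_zones(scheme)) is None

    def test_boundary_point_goes_to_inner_ring(self, scheme):
        zs = concentric_zones(scheme)
        assert zone_of(Point(100, 0), zs) == 1
        assert zone_of(Point(200, 0), zs) == 2

    def test_vectorized_matches_scalar(self, scheme):
        zs = concentric_zones(scheme)
        pts = np.array([(0, 0), (150, 0), (250, 0), (400, 0), (100, 0)])
        vec = zones_of_points(pts, zs)
        for p, z in zip(pts, vec):
            assert (zone_of(Point(p), zs) or 0) == z


class TestSupplyRatio:
    def test_as_printed_direct_division(self, scheme):
        zs = concentric_zones(scheme)
        r = supply_ratio(site_at((0, 0)), zs, [unit_at((50, 0), 100)],
                         scheme, Group.AGE15_64, "as_printed")
        assert r.R == pytest.approx(0.01)

    def test_weighted_unit_in_second_ring(self, scheme):
        zs = concentric_zones(scheme)
        r = supply_ratio(site_at((0, 0)), zs, [unit_at((150, 0), 100)],
                         scheme, Group.AGE15_64, "weighted")
        assert r.R == pytest.approx(1.0 / (100 * 0.68))

    def test_empty_catchment_gives_zero_not_infinity(self, scheme):
        zs = concentric_zones(scheme)
        r = supply_ratio(site_at((0, 0)), zs, [unit_at((5000, 0), 100)],
                         scheme, Group.AGE15_64)
        assert r.R == 0.0

    def test_unknown_variant_is_an_error(self, scheme):
        with pytest.raises(ConfigError):
            supply_ratio(site_at((0, 0)), concentric_zones(scheme), [],
                         scheme, Group.AGE15_64, "bogus")

    def test_both_variants_match_brute_force_on_random_instance(self, scheme):
        rng = np.random.default_rng(17)
        road, sites, units, site_nodes, unit_nodes = lattice_instance(
            rng, n_sites=5, n_units=12)
        times = time_matrix(road, site_nodes)
        zs = compute_zone_sets(sites, "drive", road, None, scheme)
        for variant in ("as_printed", "weighted"):
            brute = brute_force_ratios(sites, site_nodes, units, unit_nodes,
                                       times, scheme, Group.AGE15_64, variant)
            for s in sites:
                got = supply_ratio(s, zs[s.site_id], units, scheme,
                                   Group.AGE15_64, variant)
                assert got.R == pytest.approx(brute[s.site_id], abs=1e-15)


class TestAccessibilityAt:
    def test_no_reachable_site_gives_zero(self, scheme):
        zs = {"s": concentric_zones(scheme)}
        from fca_access.model import SupplyRatio
        ratios = {"s": SupplyRatio(site_id="s", R=0.01)}
        assert accessibility_at(Point(5000, 0), zs, ratios, scheme) == 0.0

    def test_single_site_second_ring_weighting(self, scheme):
        from fca_access.model import SupplyRatio
        zs = {"s": concentric_zones(scheme)}
        ratios = {"s": SupplyRatio(site_id="s", R=0.01)}
        assert accessibility_at(Point(150, 0), zs, ratios, scheme) == \
            pytest.approx(0.0068)

    def test_additivity_over_sites(self, scheme):
        from fca_access.model import CatchmentZoneSet, SupplyRatio
        z1 = concentric_zones(scheme)
        hulls = [box(600 - r, -r, 600 + r, r) for r in (400.0, 500.0, 620.0)]
        rings = [hulls[0]] + [o.difference(i) for i, o in zip(hulls, hulls[1:])]
        z2 = CatchmentZoneSet(site_id="s2", hulls=hulls, rings=rings, scheme=scheme)
        zs = {"s1": z1, "s2": z2}
        ratios = {k: SupplyRatio(site_id=k, R=0.01) for k in zs}
        # point (50, 0): ring 1 of s1, ring 3 of s2
        assert accessibility_at(Point(50, 0), zs, ratios, scheme) == \
            pytest.approx(0.01 * 1.0 + 0.01 * 0.22)


class TestHexGrid:
    def test_kept_cell_points_lie_inside_region(self):
        region = box(0, 0, 1000, 1000)
        grid = hex_grid(region, 500.0)
        for c in grid.cells:
            assert region.covers(Point(c.point))

    def test_full_exclusion_mask_empties_the_grid(self):
        region = box(0, 0, 1000, 1000)
        grid = hex_grid(region, 500.0, exclusion_mask=box(-10, -10, 1010, 1010))
        assert grid.n_cells == 0

    def test_tiling_covers_bounding_box(self):
        from shapely.ops import unary_union
        cells = hex_tiling(0, 0, 1000, 700, 250.0)
        union = unary_union([c.polygon for c in cells])
        bbox = box(0, 0, 1000, 700)
        covered = union.intersection(bbox).area
        assert covered == pytest.approx(bbox.area, rel=1e-6)

    def test_cell_width_is_across_flats(self):
        cells = hex_tiling(0, 0, 100, 100, 250.0)
        minx, miny, maxx, maxy = cells[0].polygon.bounds
        assert maxy - miny == pytest.approx(250.0)          # across flats
        assert maxx - minx == pytest.approx(2 * 250.0 / math.sqrt(3))

    def test_degenerate_region_is_an_error(self):
        with pytest.raises(Exception):
            hex_grid(Point(0, 0), 500.0)


class TestSurface:
    def test_disallowed_service_group_pair_is_an_error(self, scheme):
        sc = gen_scenario("city", 1)
        grid = hex_grid(sc.region, 2000.0)
        with pytest.raises(ConfigError, match="plwh"):
            surface(Service.TESTING, Group.PLWH, sc.sites, sc.units, grid,
                    scheme, network=sc.road)

    def test_single_central_site_decays_in_steps_along_a_ray(self, scheme):
        """With one site, A must step down 1 : 0.68 : 0.22 : 0 across rings."""
        cfg = ScenarioConfig(grid_nx=9, grid_ny=9, spacing_m=1500.0,
                             road_speed_kmh=15.0, jitter_frac=0.0, seed=0)
        road = gen_road_network(cfg)
        center = (cfg.width_m / 2, cfg.height_m / 2)
        sites = [site_at(center)]
        units = [unit_at(center, 100)]
        zs = compute_zone_sets(sites, "drive", road, None, scheme)
        r = supply_ratio(sites[0], zs["s"], units, scheme, Group.AGE15_64)
        # 6 min/edge: zone hulls along the +x axis reach 1, 3, and 4 grid
        # steps (grid edge); sample strictly inside each ring
        ray_a = []
        for dist in (750.0, 2250.0, 5000.0, 20_000.0):
            p = Point(center[0] + dist, center[1])
            ray_a.append(accessibility_at(p, zs, {"s": r}, scheme))
        expected = [r.R * w for w in (1.0, 0.68, 0.22)] + [0.0]
        assert ray_a == pytest.approx(expected)
        assert ray_a[0] > ray_a[1] > ray_a[2] > ray_a[3] == 0.0

    def test_duplicating_every_site_doubles_every_cell(self, scheme):
        sc = gen_scenario("city", 4)
        grid = hex_grid(sc.region, 1500.0)
        base = surface(Service.TESTING, Group.AGE15_64, sc.sites[:8], sc.units,
                       grid, scheme, network=sc.road)
        doubled_sites = sc.sites[:8] + [
            ServiceSite(site_id=s.site_id + "_dup", x=s.x, y=s.y,
                        services=s.services, capacity=s.capacity)
            for s in sc.sites[:8]]
        doubled = surface(Service.TESTING, Group.AGE15_64, doubled_sites,
                          sc.units, grid, scheme, network=sc.road)
        assert np.allclose(doubled.A, 2.0 * base.A, rtol=1e-12)

    def test_adding_a_site_never_decreases_accessibility(self, scheme):
        sc = gen_scenario("city", 4)
        grid = hex_grid(sc.region, 1500.0)
        base = surface(Service.TESTING, Group.AGE15_64, sc.sites[:6], sc.units,
                       grid, scheme, network=sc.road)
        more = surface(Service.TESTING, Group.AGE15_64, sc.sites[:7], sc.units,
                       grid, scheme, network=sc.road)
        assert np.all(more.A >= base.A - 1e-15)

    def test_increasing_population_never_increases_accessibility(self, scheme):
        sc = gen_scenario("city", 4)
        grid = hex_grid(sc.region, 1500.0)
        base = surface(Service.TESTING, Group.AGE15_64, sc.sites[:6], sc.units,
                       grid, scheme, network=sc.road)
        bumped = [PopulationUnit(unit_id=u.unit_id, geometry=u.geometry,
                                 counts=dict(u.counts,
                                             **{Group.AGE15_64:
                                                u.count(Group.AGE15_64) + 500}))
                  for u in sc.units]
        more_demand = surface(Service.TESTING, Group.AGE15_64, sc.sites[:6],
                              bumped, grid, scheme, network=sc.road)
        assert np.all(more_demand.A <= base.A + 1e-15)

    def test_conservation_of_delivered_supply_weighted_variant(self, scheme):
        """sum_i P_i A_i = sum_j S_j when both steps use the same decay
        weights and demand points are the unit centroids."""
        sc = gen_scenario("city", 4)
        sites = sc.sites[:10]
        zs = compute_zone_sets(sites, "drive", sc.road, None, scheme)
        ratios = {s.site_id: supply_ratio(s, zs[s.site_id], sc.units, scheme,
                                          Group.AGE15_64, "weighted")
                  for s in sites}
        delivered = sum(
            u.count(Group.AGE15_64)
            * accessibility_at(unit_centroid(u), zs, ratios, scheme)
            for u in sc.units)
        supplied = sum(s.capacity for s in sites if ratios[s.site_id].R > 0)
        assert delivered == pytest.approx(supplied, abs=1e-9)


class TestNormalize:
    def test_min_max_scaling(self, scheme):
        grid = hex_grid(box(0, 0, 1000, 1000), 400.0)
        from fca_access.model import AccessibilitySurface
        vals = np.linspace(0, 2, grid.n_cells)
        surf = normalize(AccessibilitySurface(grid=grid, A=vals))
        assert surf.A_normalized.min() == 0.0
        assert surf.A_normalized.max() == 1.0
        assert np.allclose(surf.A_normalized, vals / 2.0)

    def test_constant_surface_normalizes_to_zero(self, scheme):
        grid = hex_grid(box(0, 0, 1000, 1000), 400.0)
        from fca_access.model import AccessibilitySurface
        surf = normalize(AccessibilitySurface(grid=grid,
                                              A=np.full(grid.n_cells, 3.0)))
        assert np.all(surf.A_normalized == 0.0)

    def test_invariant_under_uniform_capacity_rescaling(self, scheme):
        sc = gen_scenario("city", 4)
        grid = hex_grid(sc.region, 1500.0)
        base = normalize(surface(Service.TESTING, Group.AGE15_64, sc.sites[:8],
                                 sc.units, grid, scheme, network=sc.road))
        scaled_sites = [ServiceSite(site_id=s.site_id, x=s.x, y=s.y,
                                    services=s.services, capacity=s.capacity * 7.5)
                        for s in sc.sites[:8]]
        scaled = normalize(surface(Service.TESTING, Group.AGE15_64, scaled_sites,
                                   sc.units, grid, scheme, network=sc.road))
        assert np.allclose(base.A_normalized, scaled.A_normalized, atol=1e-12)
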