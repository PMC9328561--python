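"""Travel times, nearest-node snapping, catchment zone construction."""

import itertools
import math

import networkx as nx
import numpy as np
import pytest
from shapely.geometry import Point

from fca_access.errors import DataError
from fca_access.model import (
    MILE_M,
    RoadEdge,
    RoadNetwork,
    Service,
    ServiceSite,
    TransitNetwork,
    TravelZoneScheme,
)
from fca_access.synthetic import ScenarioConfig, gen_road_network
from fca_access.travel import (
    catchment_zones,
    nearest_node,
    nearest_stop,
    shortest_times,
    transit_catchment_zones,
    transit_time,
)

from conftest import shared_transit_from_road


def path_network(n=3, edge_min=5.0, spacing=1000.0):
    """Straight path a-b-c-... with a fixed travel time per edge."""
    names = [chr(ord("a") + i) for i in range(n)]
    nodes = {nm: (i * spacing, 0.0) for i, nm in enumerate(names)}
    speed = spacing / 1000.0 * 60.0 / edge_min  # km/h giving edge_min minutes
    edges = [RoadEdge(u=names[i], v=names[i + 1], length_m=spacing, speed_kmh=speed)
             for i in range(n - 1)]
    return RoadNetwork(nodes=nodes, edges=edges)


class TestShortestTimes:
    def test_hand_path_times(self):
        net = path_network(3, edge_min=5.0)
        assert shortest_times(net, "a", 30.0) == pytest.approx(
            {"a": 0.0, "b": 5.0, "c": 10.0})

    def test_cutoff_excludes_unreachable_nodes(self):
        net = path_network(3, edge_min=5.0)
        assert set(shortest_times(net, "a", 4.0)) == {"a"}

    def test_missing_source_is_an_error(self):
        with pytest.raises(DataError):
            shortest_times(path_network(3), "zz", 30.0)

    def test_agrees_with_exhaustive_path_enumeration(self):
        """Dijkstra times equal a brute-force minimum over all simple paths
        on a small random connected graph."""
        rng = np.random.default_rng(4)
        n = 9
        nodes = {f"n{i}": (float(rng.uniform(0, 1000)), float(rng.uniform(0, 1000)))
                 for i in range(n)}
        ids = sorted(nodes)
        edges = []
        for i in range(1, n):  # random spanning tree + extra chords
            j = int(rng.integers(0, i))
            edges.append((ids[i], ids[j]))
        for _ in range(6):
            i, j = rng.choice(n, 2, replace=False)
            if (ids[i], ids[j]) not in edges and (ids[j], ids[i]) not in edges:
                edges.append((ids[int(i)], ids[int(j)]))
        net = RoadNetwork(nodes=nodes, edges=[
            RoadEdge(u=u, v=v, length_m=float(rng.uniform(100, 2000)),
                     speed_kmh=30.0) for u, v in edges])
        g = net.graph()
        times = shortest_times(net, ids[0], cutoff_min=1e9)
        for target in ids:
            best = math.inf if target != ids[0] else 0.0
            for path in nx.all_simple_paths(g, ids[0], target):
                t = sum(g[a][b]["travel_time_min"] for a, b in zip(path, path[1:]))
                best = min(best, t)
            if math.isinf(best):
                assert target not in times
            else:
                assert times[target] == pytest.approx(best)

    def test_triangle_inequality_on_sampled_triples(self):
        road = gen_road_network(ScenarioConfig(grid_nx=6, grid_ny=6, seed=8))
        ids = sorted(road.nodes)
        rng = np.random.default_rng(0)
        full = {i: shortest_times(road, i, 1e9) for i in ids}
        for _ in range(50):
            a, b, c = (ids[int(k)] for k in rng.choice(len(ids), 3, replace=False))
            assert full[a][c] <= full[a][b] + full[b][c] + 1e-9


class TestNearest:
    def test_coincident_point_maps_to_its_node(self):
        net = path_network(3)
        assert nearest_node(Point(1000.0, 0.0), net) == "b"

    def test_equidistant_tie_broken_by_smallest_id(self):
        net = RoadNetwork(
            nodes={"a": (0.0, 0.0), "b": (2.0, 0.0)},
            edges=[RoadEdge(u="a", v="b", length_m=2.0, speed_kmh=10.0)])
        assert nearest_node(Point(1.0, 0.0), net) == "a"

    def test_agrees_with_linear_scan_on_random_points(self):
        road = gen_road_network(ScenarioConfig(grid_nx=7, grid_ny=7, seed=2))
        rng = np.random.default_rng(1)
        for _ in range(100):
            p = Point(rng.uniform(0, 3600), rng.uniform(0, 3600))
            best = min(road.nodes,
                       key=lambda n: (math.hypot(road.nodes[n][0] - p.x,
                                                 road.nodes[n][1] - p.y), n))
            assert nearest_node(p, road) == best

    def test_empty_network_is_an_error(self):
        with pytest.raises(DataError):
            nearest_stop(Point(0, 0), TransitNetwork(stops={}, links=[]))


def _site(x, y):
    return ServiceSite(site_id="s", x=x, y=y, services=frozenset({Service.TESTING}))


class TestCatchmentZones:
    def test_three_noncollinear_nodes_give_triangular_hull(self, scheme):
        nodes = {"a": (0.0, 0.0), "b": (1000.0, 0.0), "c": (0.0, 1000.0)}
        edges = [RoadEdge(u="a", v="b", length_m=1000.0, speed_kmh=12.0),
                 RoadEdge(u="a", v="c", length_m=1000.0, speed_kmh=12.0)]
        net = RoadNetwork(nodes=nodes, edges=edges)  # 5 min per edge
        zs = catchment_zones(_site(0, 0), net, scheme)
        assert zs.hulls[0].equals_exact(
            type(zs.hulls[0])([(0, 0), (1000, 0), (0, 1000)]), 1e-9) or \
            zs.hulls[0].area == pytest.approx(500_000.0)

    def test_single_reachable_node_buffered_to_disk(self, scheme):
        net = path_network(3, edge_min=40.0)  # neighbors beyond threshold
        zs = catchment_zones(_site(0, 0), net, scheme)
        eps = net.median_edge_length() / 2.0
        assert zs.hulls[0].area == pytest.approx(math.pi * eps**2, rel=0.01)
        assert zs.hulls[0].contains(Point(0, 0))

    def test_hull_areas_nondecreasing_on_random_scenarios(self, scheme):
        rng = np.random.default_rng(6)
        for rep in range(20):
            cfg = ScenarioConfig(
                grid_nx=int(rng.integers(4, 8)), grid_ny=int(rng.integers(4, 8)),
                spacing_m=float(rng.integers(400, 1500)),
                road_speed_kmh=float(rng.integers(10, 50)),
                seed=int(rng.integers(100_000)))
            road = gen_road_network(cfg)
            x = float(rng.uniform(0, cfg.width_m))
            y = float(rng.uniform(0, cfg.height_m))
            zs = catchment_zones(_site(x, y), road, scheme)
            areas = [h.area for h in zs.hulls]
            assert areas[0] <= areas[1] * (1 + 1e-12)
            assert areas[1] <= areas[2] * (1 + 1e-12)
            for inner, outer in zip(zs.hulls, zs.hulls[1:]):
                assert outer.covers(inner)

    def test_rings_partition_the_outer_hull(self, scheme):
        road = gen_road_network(ScenarioConfig(grid_nx=6, grid_ny=6, seed=5))
        zs = catchment_zones(_site(1500, 1500), road, scheme)
        union_area = sum(r.area for r in zs.rings)
        assert union_area == pytest.approx(zs.outer.area, rel=1e-9)
        for r1, r2 in itertools.combinations(zs.rings, 2):
            assert r1.intersection(r2).area == pytest.approx(0.0, abs=1e-6)


class TestTransitTime:
    def line(self, n, spacing=MILE_M):
        stops = {f"t{i}": (i * spacing, 0.0) for i in range(n)}
        links = [(f"t{i}", f"t{i+1}", spacing) for i in range(n - 1)]
        return TransitNetwork(stops=stops, links=links)

    def test_shared_nearest_stop_gives_zero(self):
        net = self.line(2)
        assert transit_time(Point(10, 0), Point(-5, 5), net) == 0.0

    def test_one_mile_at_10mph_is_six_minutes(self):
        net = self.line(2, spacing=1609.34)
        t = transit_time(Point(0, 0), Point(1609.34, 0), net)
        assert t == pytest.approx(6.0, abs=1e-3)

    def test_additivity_along_three_stop_path(self):
        net = self.line(3, spacing=804.67)
        t = transit_time(Point(0, 0), Point(2 * 804.67, 0), net)
        assert t == pytest.approx(6.0, abs=1e-3)

    def test_disconnected_stops_give_infinity(self):
        stops = {"a": (0.0, 0.0), "b": (100.0, 0.0), "c": (10_000.0, 0.0),
                 "d": (10_100.0, 0.0)}
        net = TransitNetwork(stops=stops, links=[("a", "b", 100.0),
                                                 ("c", "d", 100.0)])
        assert math.isinf(transit_time(Point(0, 0), Point(10_000, 0), net))


class TestTransitCatchments:
    def test_ten_stop_line_hull_spans_10min_reach(self, scheme):
        # 1-mile spacing at 10 mph: 6 min per link, so 10 min reaches 1 stop
        # (1.667-mile radius truncated to the last whole stop)
        stops = {f"t{i}": (i * MILE_M, 0.0) for i in range(10)}
        links = [(f"t{i}", f"t{i+1}", MILE_M) for i in range(9)]
        net = TransitNetwork(stops=stops, links=links)
        zs = transit_catchment_zones(_site(5 * MILE_M, 0.0), net, scheme)
        minx, _, maxx, _ = zs.hulls[0].bounds
        eps = MILE_M / 2.0
        assert minx == pytest.approx(4 * MILE_M - eps, rel=0.01)
        assert maxx == pytest.approx(6 * MILE_M + eps, rel=0.01)

    def test_unreachable_far_stop_gives_disk_around_origin(self, scheme):
        # stop b is 50 km away: > 30 min at 10 mph, so only the origin stop
        # is reachable and the catchment degenerates to an eps-disk
        stops = {"a": (0.0, 0.0), "b": (50_000.0, 0.0)}
        net = TransitNetwork(stops=stops, links=[("a", "b", 50_000.0)])
        zs = transit_catchment_zones(_site(0, 0), net, scheme)
        eps = 25_000.0  # half the (single) median link length
        assert zs.hulls[0].contains(Point(0, 0))
        assert zs.hulls[-1].area == pytest.approx(math.pi * eps**2, rel=0.01)
        assert not zs.hulls[-1].contains(Point(50_000.0, 0.0))

    def test_transit_hulls_within_drive_hulls_on_shared_geometry(self, scheme):
        cfg = ScenarioConfig(grid_nx=7, grid_ny=7, spacing_m=500.0,
                             road_speed_kmh=25.0, seed=12)
        road = gen_road_network(cfg)
        transit = shared_transit_from_road(road, mph=10.0)  # 16.1 km/h < 25
        site = _site(1600.0, 1600.0)
        zd = catchment_zones(site, road, scheme)
        zt = transit_catchment_zones(site, transit, scheme)
        for hd, ht in zip(zd.hulls, zt.hulls):
            assert hd.buffer(1e-6).covers(ht)
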