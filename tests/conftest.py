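"""Shared fixtures and independent-oracle helpers.

The brute-force helpers here recompute supply ratios and accessibility
directly from a travel-time matrix (no catchment polygons), providing an
independent route against which the polygon-based implementation is checked.
"""

from __future__ import annotations

import logging

import networkx as nx
import numpy as np
import pytest
from shapely.geometry import Point

from fca_access.model import (
    Group,
    PopulationUnit,
    RoadNetwork,
    Service,
    ServiceSite,
    TransitNetwork,
    TravelZoneScheme,
)
from fca_access.synthetic import ScenarioConfig, gen_road_network

logging.disable(logging.WARNING)


@pytest.fixture
def scheme() -> TravelZoneScheme:
    return TravelZoneScheme()


def shared_transit_from_road(road: RoadNetwork, mph: float = 10.0) -> TransitNetwork:
    """Transit network with stops at every road node and links on every road
    edge: shared geometry, different speed."""
    stops = {f"s_{n}": xy for n, xy in road.nodes.items()}
    links = [(f"s_{e.u}", f"s_{e.v}", e.length_m) for e in road.edges]
    return TransitNetwork(stops=stops, links=links, constant_speed_mph=mph)


def lattice_instance(rng: np.random.Generator, n_sites: int = 4,
                     n_units: int = 12, grid_n: tuple[int, int] | None = None,
                     service: Service = Service.TESTING):
    """Random exact-lattice instance (no jitter, uniform speed) with sites
    and unit centroids placed on network nodes, so geometric zone assignment
    and travel-time zone assignment provably agree."""
    n = int(rng.integers(5, 8)) if grid_n is None else grid_n[0]
    m = n if grid_n is None else grid_n[1]
    cfg = ScenarioConfig(
        grid_nx=n, grid_ny=m,
        spacing_m=float(rng.integers(400, 900)),
        road_speed_kmh=float(rng.integers(15, 40)),
        jitter_frac=0.0, n_sites=n_sites, n_units=9,
        seed=int(rng.integers(100_000)))
    road = gen_road_network(cfg)
    node_ids = sorted(road.nodes)
    site_nodes = [node_ids[int(i)]
                  for i in rng.choice(len(node_ids), n_sites, replace=False)]
    sites = [ServiceSite(site_id=f"x{i}", x=road.nodes[nd][0], y=road.nodes[nd][1],
                         services=frozenset({service}))
             for i, nd in enumerate(site_nodes)]
    unit_nodes = [node_ids[int(i)]
                  for i in rng.choice(len(node_ids), n_units, replace=False)]
    units = [PopulationUnit(unit_id=f"u{i}", geometry=Point(road.nodes[nd]),
                            counts={Group.AGE15_64: int(rng.integers(10, 500))})
             for i, nd in enumerate(unit_nodes)]
    return road, sites, units, site_nodes, unit_nodes


def time_matrix(road: RoadNetwork, source_nodes) -> dict[str, dict[str, float]]:
    g = road.graph()
    return {nd: nx.single_source_dijkstra_path_length(g, nd, weight="travel_time_min")
            for nd in source_nodes}


def brute_force_ratios(sites, site_nodes, units, unit_nodes, times,
                       scheme: TravelZoneScheme, group: Group,
                       variant: str) -> dict[str, float]:
    """Eq-1 supply ratios straight from the time matrix (no polygons)."""
    out = {}
    for s, nd in zip(sites, site_nodes):
        denom = 0.0
        for u, un in zip(units, unit_nodes):
            t = times[nd].get(un)
            r = scheme.zone_of_time(t) if t is not None else None
            if r is None:
                continue
            p = u.count(group)
            denom += p if variant == "as_printed" else p * scheme.weight_of_zone(r)
        out[s.site_id] = 0.0 if denom == 0.0 else s.capacity / denom
    return out


def brute_force_accessibility(site_ids, site_nodes, ratios, times,
                              scheme: TravelZoneScheme, demand_node: str) -> float:
    """Eq-2 accessibility at a node straight from the time matrix."""
    total = 0.0
    for sid, nd in zip(site_ids, site_nodes):
        t = times[nd].get(demand_node)
        r = scheme.zone_of_time(t) if t is not None else None
        if r is not None:
            total += ratios[sid] * scheme.weight_of_zone(r)
    return total
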