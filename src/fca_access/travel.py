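"""Travel times and catchment delineation for driving and transit modes.

Driving uses Dijkstra shortest paths over road-edge travel times. Transit
uses shortest stop-to-stop path length over the stop graph divided by a
constant speed (default 10 mph); access/egress legs are excluded by default,
matching a stop-to-stop travel-time model, but a finite ``walk_speed_kmh``
adds straight-line walk legs.

A site's catchment for zone break r is the convex hull of network nodes (or
transit stops) reachable within r minutes. Reachable sets are nested in the
cutoff, so hulls are nested; degenerate hulls (fewer than 3 non-collinear
points) are buffered to a small disk/capsule so every site has a
nonzero-area catchment.
"""

from __future__ import annotations

import logging
import math
from typing import Mapping, Optional

import networkx as nx
import numpy as np
from shapely.geometry import MultiPoint, Point
from shapely.geometry.base import BaseGeometry
from shapely.ops import unary_union

from .errors import DataError
from .model import (
    CatchmentZoneSet,
    RoadNetwork,
    ServiceSite,
    TransitNetwork,
    TravelZoneScheme,
)

logger = logging.getLogger(__name__)

HULL_BUFFER_QUAD_SEGS = 16


def shortest_times(network: RoadNetwork, source_node: str,
                   cutoff_min: float) -> dict[str, float]:
    """Single-source travel times (minutes) to all nodes within ``cutoff_min``.

    The source itself is included with time 0.
    """
    if source_node not in network.nodes:
        raise DataError(f"source node {source_node!r} not in network")
    if not cutoff_min > 0:
        raise DataError("cutoff must be positive")
    times = nx.single_source_dijkstra_path_length(
        network.graph(), source_node, cutoff=cutoff_min, weight="travel_time_min"
    )
    return dict(times)


def _nearest(point: Point | tuple[float, float], ids: list[str],
             coords: np.ndarray) -> str:
    if isinstance(point, Point):
        px, py = point.x, point.y
    else:
        px, py = point
    d2 = (coords[:, 0] - px) ** 2 + (coords[:, 1] - py) ** 2
    dmin = d2.min()
    # ids are pre-sorted, so the first hit is the lexicographically smallest
    return ids[int(np.argmax(d2 == dmin))]


def nearest_node(point, network: RoadNetwork) -> str:
    """Road node closest to ``point``; ties broken by smallest node id."""
    if not network.nodes:
        raise DataError("road network has no nodes")
    ids, coords = network.node_array()
    return _nearest(point, ids, coords)


def nearest_stop(point, transit: TransitNetwork) -> str:
    """Transit stop closest to ``point``; ties broken by smallest stop id."""
    if transit.is_empty:
        raise DataError("transit network has no stops")
    ids, coords = transit.stop_array()
    return _nearest(point, ids, coords)


def _hull_of_points(coords: np.ndarray, eps: float) -> BaseGeometry:
    """Convex hull of points; degenerate hulls buffered by eps to 2-D."""
    hull = MultiPoint(coords).convex_hull
    if hull.area == 0.0:
        hull = hull.buffer(eps, quad_segs=HULL_BUFFER_QUAD_SEGS)
    return hull


def _zone_set_from_times(site_id: str, times: Mapping[str, float],
                         positions: Mapping[str, tuple[float, float]],
                         scheme: TravelZoneScheme, eps: float) -> CatchmentZoneSet:
    hulls: list[BaseGeometry] = []
    for b in scheme.breaks_min:
        pts = np.array([positions[n] for n, t in sorted(times.items()) if t <= b],
                       dtype=float)
        hull = _hull_of_points(pts, eps)
        if hulls and not hull.covers(hulls[-1]):
            # reachable sets are nested so hulls are too, except when an inner
            # degenerate hull was eps-buffered; union restores nestedness
            hull = unary_union([hulls[-1], hull])
        hulls.append(hull)
    rings: list[BaseGeometry] = [hulls[0]]
    for inner, outer in zip(hulls, hulls[1:]):
        rings.append(outer.difference(inner))
    return CatchmentZoneSet(site_id=site_id, hulls=hulls, rings=rings, scheme=scheme)


def catchment_zones(site: ServiceSite, network: RoadNetwork,
                    scheme: TravelZoneScheme,
                    snap_tolerance_m: Optional[float] = None) -> CatchmentZoneSet:
    """Driving catchment zones for a site.

    The site is snapped to its nearest road node; if it lies farther than the
    snap tolerance (default 2x the median edge length) a warning is logged
    and the snap is applied anyway.
    """
    node = nearest_node(site.location, network)
    med = network.median_edge_length()
    tol = 2.0 * med if snap_tolerance_m is None else snap_tolerance_m
    nx_, ny_ = network.nodes[node]
    snap_dist = math.hypot(site.x - nx_, site.y - ny_)
    if snap_dist > tol:
        logger.warning(
            "site %s is %.0f m from nearest road node %s (tolerance %.0f m); snapping anyway",
            site.site_id, snap_dist, node, tol,
        )
    times = shortest_times(network, node, scheme.threshold_min)
    return _zone_set_from_times(site.site_id, times, network.nodes, scheme, eps=med / 2.0)


def transit_times_from(stop_id: str, transit: TransitNetwork,
                       cutoff_min: float) -> dict[str, float]:
    """Travel times (minutes) from a stop to all stops within ``cutoff_min``."""
    if stop_id not in transit.stops:
        raise DataError(f"stop {stop_id!r} not in transit network")
    cutoff_m = cutoff_min * transit.speed_m_per_min
    lengths = nx.single_source_dijkstra_path_length(
        transit.graph(), stop_id, cutoff=cutoff_m, weight="length_m"
    )
    v = transit.speed_m_per_min
    return {s: d / v for s, d in lengths.items()}


def transit_time(origin_pt, dest_pt, transit: TransitNetwork,
                 walk_speed_kmh: Optional[float] = None) -> float:
    """Stop-to-stop transit travel time in minutes between two points.

    Nearest stops are used at both ends. Disconnected stops yield +inf
    (unreachable by transit). With ``walk_speed_kmh`` set, straight-line
    access and egress walk legs are added.
    """
    if transit.is_empty:
        raise DataError("transit network has no stops")
    o = nearest_stop(origin_pt, transit)
    d = nearest_stop(dest_pt, transit)
    if o == d:
        ride = 0.0
    else:
        try:
            length = nx.shortest_path_length(transit.graph(), o, d, weight="length_m")
        except nx.NetworkXNoPath:
            return math.inf
        ride = length / transit.speed_m_per_min
    if walk_speed_kmh is not None:
        w = walk_speed_kmh * 1000.0 / 60.0  # m/min
        ox, oy = _xy(origin_pt)
        dx, dy = _xy(dest_pt)
        sox, soy = transit.stops[o]
        sdx, sdy = transit.stops[d]
        ride += math.hypot(ox - sox, oy - soy) / w
        ride += math.hypot(dx - sdx, dy - sdy) / w
    return ride


def _xy(point) -> tuple[float, float]:
    if isinstance(point, Point):
        return point.x, point.y
    return float(point[0]), float(point[1])


def transit_catchment_zones(site: ServiceSite, transit: TransitNetwork,
                            scheme: TravelZoneScheme) -> CatchmentZoneSet:
    """Transit catchment zones: hulls of stops reachable from the site's
    nearest stop within each zone break at the constant transit speed."""
    if transit.is_empty:
        raise DataError("transit network has no stops")
    origin = nearest_stop(site.location, transit)
    times = transit_times_from(origin, transit, scheme.threshold_min)
    if transit.links:
        eps = float(np.median([l for _, _, l in transit.links])) / 2.0
    else:
        eps = 100.0
    return _zone_set_from_times(site.site_id, times, transit.stops, scheme, eps=eps)
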