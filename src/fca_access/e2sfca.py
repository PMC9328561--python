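"""Enhanced two-step floating catchment area (E2SFCA) accessibility.

Step 1 computes each site j's supply-to-population ratio

    R_j = S_j / sum_{k : d_kj <= d0} P_k                    ("as_printed")
    R_j = S_j / sum_r sum_{k in zone r} P_k W_r             ("weighted")

over the population units whose centroids fall inside the site's catchment,
where d0 is the outermost zone break and W_r the distance-decay weight of
zone r. Step 2 sums, at a demand location i, the ratios of every reachable
site weighted by the zone of i in that site's catchment:

    A_i = sum_j R_j W_{r(i,j)}.

The "as_printed" variant leaves the step-1 denominator unweighted; the
"weighted" variant applies the same decay weights in both steps (the
standard E2SFCA form, for which total delivered supply is conserved:
sum_i P_i A_i = sum_j S_j). Both are provided; "as_printed" is the default.

Accessibility is aggregated onto a flat-top hexagon grid: each cell's value
is A at the cell's representative point. Hexagons reduce the orientation
bias that square grids introduce at zone edges.
"""

from __future__ import annotations

import logging
import math
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import shapely
from shapely.geometry import Point, box
from shapely.geometry.base import BaseGeometry

from .demography import unit_centroid
from .errors import ConfigError, DataError
from .model import (
    SERVICE_GROUPS,
    AccessibilitySurface,
    CatchmentZoneSet,
    Group,
    HexCell,
    HexGrid,
    PopulationUnit,
    RoadNetwork,
    Service,
    ServiceSite,
    SupplyRatio,
    TransitNetwork,
    TravelZoneScheme,
)
from .travel import catchment_zones, transit_catchment_zones

logger = logging.getLogger(__name__)

VARIANTS = ("as_printed", "weighted")


def zone_of(point, zones: CatchmentZoneSet) -> Optional[int]:
    """1-based zone index of the ring containing ``point``, or None outside.

    Boundary points belong to the innermost zone whose hull covers them.
    """
    p = point if isinstance(point, Point) else Point(point)
    for r, hull in enumerate(zones.hulls, start=1):
        if hull.covers(p):
            return r
    return None


def zones_of_points(coords: np.ndarray, zones: CatchmentZoneSet) -> np.ndarray:
    """Vectorized ``zone_of`` over an Nx2 coordinate array (0 = outside)."""
    coords = np.asarray(coords, dtype=float)
    pts = shapely.points(coords)
    out = np.zeros(len(pts), dtype=np.int64)
    for r in range(len(zones.hulls), 0, -1):  # inner hull written last wins
        covered = shapely.covers(zones.hulls[r - 1], pts)
        out[covered] = r
    return out


def supply_ratio(site: ServiceSite, zones: CatchmentZoneSet,
                 units: Sequence[PopulationUnit], scheme: TravelZoneScheme,
                 group: Group, variant: str = "as_printed") -> SupplyRatio:
    """Step 1: the site's supply-to-population ratio R_j for a demand group.

    A catchment containing no population yields R_j = 0 (logged), never an
    infinity.
    """
    if variant not in VARIANTS:
        raise ConfigError(f"unknown variant {variant!r}; expected one of {VARIANTS}")
    centroids = np.array([_pt_xy(unit_centroid(u)) for u in units], dtype=float)
    if len(units) == 0:
        zone_idx = np.zeros(0, dtype=np.int64)
    else:
        zone_idx = zones_of_points(centroids, zones)
    denom = 0.0
    for u, r in zip(units, zone_idx):
        if r == 0:
            continue
        p = u.count(group)
        denom += p if variant == "as_printed" else p * scheme.weight_of_zone(int(r))
    if denom == 0.0:
        logger.warning("site %s has zero catchment population for group %s; R set to 0",
                       site.site_id, group.value)
        return SupplyRatio(site_id=site.site_id, R=0.0)
    return SupplyRatio(site_id=site.site_id, R=site.capacity / denom)


def accessibility_at(point, zone_sets: Mapping[str, CatchmentZoneSet],
                     ratios: Mapping[str, SupplyRatio],
                     scheme: TravelZoneScheme) -> float:
    """Step 2: A at a point = sum of R_j x W_r over sites reaching the point."""
    total = 0.0
    for site_id, zones in zone_sets.items():
        r = zone_of(point, zones)
        if r is None:
            continue
        total += ratios[site_id].R * scheme.weight_of_zone(r)
    return total


def _pt_xy(p: Point) -> tuple[float, float]:
    return p.x, p.y


def hex_tiling(minx: float, miny: float, maxx: float, maxy: float,
               cell_width_m: float) -> list[HexCell]:
    """Flat-top hexagon tessellation covering (and overhanging) a bounding box.

    ``cell_width_m`` is the width across flats (the distance between the two
    horizontal edges). Cells are laid out in offset columns; ids encode the
    column/row lattice position.
    """
    if not cell_width_m > 0:
        raise ConfigError("hexagon cell width must be positive")
    if not (maxx > minx and maxy > miny):
        raise DataError("degenerate region: bounding box has no area")
    w = cell_width_m
    R = w / math.sqrt(3.0)  # circumradius
    dx = 1.5 * R
    cells: list[HexCell] = []
    ncols = int(math.ceil((maxx - minx) / dx)) + 2
    nrows = int(math.ceil((maxy - miny) / w)) + 2
    angles = [math.radians(a) for a in (0, 60, 120, 180, 240, 300)]
    for col in range(-1, ncols):
        cx = minx + col * dx
        y0 = miny + (w / 2.0 if col % 2 else 0.0)
        for row in range(-1, nrows):
            cy = y0 + row * w
            verts = [(cx + R * math.cos(a), cy + R * math.sin(a)) for a in angles]
            cells.append(HexCell(
                cell_id=f"h{col + 1:03d}_{row + 1:03d}",
                polygon=shapely.Polygon(verts),
                point=(cx, cy),
            ))
    return cells


def hex_grid(region_polygon: BaseGeometry, cell_width_m: float,
             exclusion_mask: Optional[BaseGeometry] = None) -> HexGrid:
    """Hexagon grid over a region.

    Cells are kept when their representative point (the hexagon center) lies
    in the region and outside the exclusion mask (e.g., an airport area with
    no road network).
    """
    if region_polygon is None or region_polygon.is_empty or region_polygon.area == 0:
        raise DataError("degenerate region polygon")
    minx, miny, maxx, maxy = region_polygon.bounds
    cells = hex_tiling(minx, miny, maxx, maxy, cell_width_m)
    pts = shapely.points(np.array([c.point for c in cells], dtype=float))
    keep = shapely.covers(region_polygon, pts)
    if exclusion_mask is not None and not exclusion_mask.is_empty:
        keep &= ~shapely.covers(exclusion_mask, pts)
    kept = [c for c, k in zip(cells, keep) if k]
    return HexGrid(cells=kept, width_m=cell_width_m)


def compute_zone_sets(sites: Sequence[ServiceSite], mode: str,
                      network: Optional[RoadNetwork],
                      transit: Optional[TransitNetwork],
                      scheme: TravelZoneScheme) -> dict[str, CatchmentZoneSet]:
    """Catchment zone sets for every site under one travel mode."""
    if mode == "drive":
        if network is None:
            raise ConfigError("drive mode requires a road network")
        return {s.site_id: catchment_zones(s, network, scheme) for s in sites}
    if mode == "transit":
        if transit is None or transit.is_empty:
            raise ConfigError("transit mode requires a non-empty transit network")
        return {s.site_id: transit_catchment_zones(s, transit, scheme) for s in sites}
    raise ConfigError(f"unknown travel mode {mode!r}; expected 'drive' or 'transit'")


def surface(service_type: Service, group: Group, sites: Sequence[ServiceSite],
            units: Sequence[PopulationUnit], grid: HexGrid,
            scheme: TravelZoneScheme, *, mode: str = "drive",
            network: Optional[RoadNetwork] = None,
            transit: Optional[TransitNetwork] = None,
            variant: str = "as_printed",
            zone_sets: Optional[Mapping[str, CatchmentZoneSet]] = None,
            zone_cache: Optional[Mapping[str, np.ndarray]] = None
            ) -> AccessibilitySurface:
    """Full E2SFCA surface for one (service, group, mode) combination.

    Only sites flagged for ``service_type`` contribute supply; demand is the
    ``group`` count of each population unit. Precomputed ``zone_sets`` (one
    per contributing site) may be passed to share catchments across surfaces;
    ``zone_cache`` optionally maps site ids to precomputed per-cell zone
    index arrays for this grid.
    """
    if group not in SERVICE_GROUPS[service_type]:
        allowed = ", ".join(g.value for g in SERVICE_GROUPS[service_type])
        raise ConfigError(
            f"group {group.value!r} is not analyzed for service {service_type.value!r} "
            f"(allowed: {allowed})"
        )
    offering = [s for s in sites if service_type in s.services]
    if zone_sets is None:
        zone_sets = compute_zone_sets(offering, mode, network, transit, scheme)
    ratios = {
        s.site_id: supply_ratio(s, zone_sets[s.site_id], units, scheme, group, variant)
        for s in offering
    }
    pts = grid.points()
    A = np.zeros(grid.n_cells, dtype=float)
    weights = np.array((0.0,) + tuple(scheme.weights))  # index 0 = outside
    for s in offering:
        if zone_cache is not None and s.site_id in zone_cache:
            z = zone_cache[s.site_id]
        else:
            z = zones_of_points(pts, zone_sets[s.site_id])
        A += ratios[s.site_id].R * weights[z]
    return AccessibilitySurface(
        grid=grid, A=A,
        metadata={
            "service": service_type.value, "group": group.value, "mode": mode,
            "variant": variant, "cell_width_m": grid.width_m,
            "scheme": {"breaks_min": list(scheme.breaks_min),
                       "weights": list(scheme.weights)},
            "n_sites": len(offering),
        },
    )


def normalize(surf: AccessibilitySurface) -> AccessibilitySurface:
    """Min-max normalize A into [0, 1] in place; constant surfaces become all
    zeros (logged), since no spatial contrast exists to rescale."""
    a = surf.A
    if a.size == 0:
        surf.A_normalized = np.zeros_like(a)
        return surf
    lo, hi = float(a.min()), float(a.max())
    if hi == lo:
        logger.warning("surface is constant (A = %.6g everywhere); normalized to 0", lo)
        surf.A_normalized = np.zeros_like(a)
    else:
        surf.A_normalized = (a - lo) / (hi - lo)
    return surf
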