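"""Core domain types for two-step floating catchment area accessibility analysis.

The package measures spatial access to HIV services for three demand
populations. Supply is a registry of service sites, each flagged for one or
more of three service layers (testing, Ryan White treatment, PrEP prevention)
with unit capacity by default. Demand is a set of population units (polygons
or points) carrying counts of people living with HIV (PLWH), men who have sex
with men (MSM), and adults aged 15-64. Travel is either driving on a road
network or public transit at a constant speed over a stop graph.

All coordinates are planar, in meters. Travel times are in minutes.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import networkx as nx
import numpy as np
from shapely.geometry import Point
from shapely.geometry.base import BaseGeometry

from .errors import ConfigError, DataError, ValidationError

MILE_M = 1609.344
#: meters per minute for one mile per hour
MPH_TO_M_PER_MIN = MILE_M / 60.0


class Service(str, enum.Enum):
    """Service layers offered by a site."""

    TESTING = "testing"
    TREATMENT = "treatment"
    PREVENTION = "prevention"


class Group(str, enum.Enum):
    """Demand population groups."""

    PLWH = "plwh"
    MSM = "msm"
    AGE15_64 = "pop15_64"


#: Which demand groups each service layer is analyzed for: testing and
#: prevention (PrEP) for MSM and the general 15-64 population, treatment
#: (Ryan White program) for PLWH.
SERVICE_GROUPS: dict[Service, tuple[Group, ...]] = {
    Service.TESTING: (Group.MSM, Group.AGE15_64),
    Service.PREVENTION: (Group.MSM, Group.AGE15_64),
    Service.TREATMENT: (Group.PLWH,),
}


def service_group_pairs() -> list[tuple[Service, Group]]:
    """The five (service, group) analysis pairs, in a fixed order."""
    return [(s, g) for s in Service for g in SERVICE_GROUPS[s]]


@dataclass(frozen=True)
class TravelZoneScheme:
    """Travel-time zones and their distance-decay weights.

    Zone r covers travel times in (breaks_min[r-2], breaks_min[r-1]] (zone 1
    starts at 0). The last break is the catchment threshold d0 beyond which a
    site is considered inaccessible. Defaults are the standard 10/20/30 minute
    zones with fast-decay weights 1, 0.68, 0.22.
    """

    breaks_min: tuple[float, ...] = (10.0, 20.0, 30.0)
    weights: tuple[float, ...] = (1.0, 0.68, 0.22)

    def __post_init__(self) -> None:
        if len(self.breaks_min) != len(self.weights):
            raise ConfigError("breaks_min and weights must have the same length")
        if not self.breaks_min:
            raise ConfigError("at least one travel zone is required")
        if any(b <= 0 for b in self.breaks_min):
            raise ConfigError("zone breaks must be positive")
        if any(b2 <= b1 for b1, b2 in zip(self.breaks_min, self.breaks_min[1:])):
            raise ConfigError("zone breaks must be strictly increasing")
        if any(not (0.0 < w <= 1.0) for w in self.weights):
            raise ConfigError("zone weights must lie in (0, 1]")
        if any(w2 > w1 for w1, w2 in zip(self.weights, self.weights[1:])):
            raise ConfigError("zone weights must be non-increasing")

    @property
    def threshold_min(self) -> float:
        """Catchment threshold d0: the outermost zone break, in minutes."""
        return self.breaks_min[-1]

    @property
    def n_zones(self) -> int:
        return len(self.breaks_min)

    def weight_of_zone(self, r: int) -> float:
        """Decay weight for 1-based zone index r."""
        return self.weights[r - 1]

    def zone_of_time(self, t_min: float) -> Optional[int]:
        """1-based zone index for a travel time, or None beyond the threshold."""
        for r, b in enumerate(self.breaks_min, start=1):
            if t_min <= b:
                return r
        return None


@dataclass(frozen=True)
class ServiceSite:
    """A service location with its offered layers and capacity S_j (default 1)."""

    site_id: str
    x: float
    y: float
    services: frozenset[Service]
    capacity: float = 1.0

    def __post_init__(self) -> None:
        if not self.services:
            raise ValidationError(f"site {self.site_id!r} offers no services")
        if not self.capacity > 0:
            raise ValidationError(f"site {self.site_id!r} has non-positive capacity")
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValidationError(f"site {self.site_id!r} has non-finite coordinates")

    @property
    def location(self) -> Point:
        return Point(self.x, self.y)


@dataclass
class PopulationUnit:
    """A demand unit: geometry plus per-group population counts.

    Optional fields (male_pop, households, ssm_households, urbanicity) feed
    the small-area MSM estimator.
    """

    unit_id: str
    geometry: BaseGeometry
    counts: dict[Group, int] = field(default_factory=dict)
    male_pop: Optional[int] = None
    households: Optional[int] = None
    ssm_households: Optional[int] = None
    urbanicity: Optional[str] = None

    def __post_init__(self) -> None:
        if self.geometry is None or self.geometry.is_empty:
            raise ValidationError(f"unit {self.unit_id!r} has empty geometry")
        for g, c in self.counts.items():
            if not isinstance(c, (int, np.integer)) or isinstance(c, bool):
                raise ValidationError(
                    f"unit {self.unit_id!r}: count for {g.value} is not an integer"
                )
            if c < 0:
                raise ValidationError(
                    f"unit {self.unit_id!r}: negative count for {g.value}"
                )
        msm = self.counts.get(Group.MSM)
        adults = self.counts.get(Group.AGE15_64)
        if msm is not None and adults is not None and msm > adults:
            raise ValidationError(
                f"unit {self.unit_id!r}: MSM count {msm} exceeds population 15-64 {adults}"
            )

    def count(self, group: Group) -> int:
        return int(self.counts.get(group, 0))


@dataclass(frozen=True)
class RoadEdge:
    u: str
    v: str
    length_m: float
    speed_kmh: float

    @property
    def travel_time_min(self) -> float:
        return self.length_m / (self.speed_kmh * 1000.0 / 60.0)


@dataclass
class RoadNetwork:
    """Road graph: nodes with planar coordinates, edges with length and speed."""

    nodes: dict[str, tuple[float, float]]
    edges: list[RoadEdge]
    directed: bool = False
    _graph: Optional[nx.Graph] = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        for e in self.edges:
            if e.u not in self.nodes or e.v not in self.nodes:
                raise DataError(f"edge ({e.u!r}, {e.v!r}) references a missing node")
            if not e.length_m > 0:
                raise DataError(f"edge ({e.u!r}, {e.v!r}) has non-positive length")
            if not e.speed_kmh > 0:
                raise DataError(f"edge ({e.u!r}, {e.v!r}) has non-positive speed")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def graph(self) -> nx.Graph:
        """networkx view with `travel_time_min` edge weights (cached)."""
        if self._graph is None:
            g: nx.Graph = nx.DiGraph() if self.directed else nx.Graph()
            g.add_nodes_from(self.nodes)
            for e in self.edges:
                g.add_edge(e.u, e.v, length_m=e.length_m,
                           travel_time_min=e.travel_time_min)
            self._graph = g
        return self._graph

    def median_edge_length(self) -> float:
        if not self.edges:
            raise DataError("network has no edges")
        return float(np.median([e.length_m for e in self.edges]))

    def node_array(self) -> tuple[list[str], np.ndarray]:
        """Node ids (sorted) and matching Nx2 coordinate array."""
        ids = sorted(self.nodes)
        return ids, np.array([self.nodes[i] for i in ids], dtype=float)


@dataclass
class TransitNetwork:
    """Transit stop graph traversed at a constant speed (default 10 mph).

    Links are undirected stop-to-stop segments; timetable information is not
    used. ``routes`` optionally records the stop sequence of each route for
    GTFS serialization.
    """

    stops: dict[str, tuple[float, float]]
    links: list[tuple[str, str, float]]
    constant_speed_mph: float = 10.0
    routes: list[tuple[str, list[str]]] = field(default_factory=list)
    _graph: Optional[nx.Graph] = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if not self.constant_speed_mph > 0:
            raise ConfigError("transit constant speed must be positive")
        for u, v, length in self.links:
            if u not in self.stops or v not in self.stops:
                raise DataError(f"transit link ({u!r}, {v!r}) references a missing stop")
            if not length > 0:
                raise DataError(f"transit link ({u!r}, {v!r}) has non-positive length")

    @property
    def is_empty(self) -> bool:
        return not self.stops

    @property
    def speed_m_per_min(self) -> float:
        return self.constant_speed_mph * MPH_TO_M_PER_MIN

    def graph(self) -> nx.Graph:
        if self._graph is None:
            g = nx.Graph()
            g.add_nodes_from(self.stops)
            for u, v, length in self.links:
                g.add_edge(u, v, length_m=length)
            self._graph = g
        return self._graph

    def stop_array(self) -> tuple[list[str], np.ndarray]:
        ids = sorted(self.stops)
        return ids, np.array([self.stops[i] for i in ids], dtype=float)


@dataclass
class CatchmentZoneSet:
    """Per-site nested travel-zone polygons.

    ``hulls[r-1]`` is the convex hull of nodes reachable within break r
    (nested, non-decreasing in area); ``rings[r-1]`` is the annulus
    hull_r minus hull_{r-1} (ring 1 equals hull 1). Boundary points belong to
    the innermost zone that covers them.
    """

    site_id: str
    hulls: list[BaseGeometry]
    rings: list[BaseGeometry]
    scheme: TravelZoneScheme

    @property
    def outer(self) -> BaseGeometry:
        return self.hulls[-1]


@dataclass(frozen=True)
class SupplyRatio:
    """Step-1 output: a site's supply-to-population ratio R_j >= 0."""

    site_id: str
    R: float

    def __post_init__(self) -> None:
        if self.R < 0:
            raise ValidationError(f"negative supply ratio for site {self.site_id!r}")


@dataclass
class HexCell:
    cell_id: str
    polygon: BaseGeometry
    point: tuple[float, float]


@dataclass
class HexGrid:
    """Flat-top hexagon tessellation; ``width_m`` is the width across flats."""

    cells: list[HexCell]
    width_m: float

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def points(self) -> np.ndarray:
        return np.array([c.point for c in self.cells], dtype=float)


@dataclass
class AccessibilitySurface:
    """Hexagon accessibility surface: per-cell A_i and min-max normalized A_i."""

    grid: HexGrid
    A: np.ndarray
    A_normalized: Optional[np.ndarray] = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)
        if len(self.A) != self.grid.n_cells:
            raise DataError("surface value count does not match grid cell count")
        if np.any(self.A < 0):
            raise ValidationError("accessibility values must be non-negative")

    @property
    def cell_ids(self) -> list[str]:
        return [c.cell_id for c in self.grid.cells]
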