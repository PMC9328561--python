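"""Seeded synthetic-city generator.

Emulates the inputs a city- or state-scale accessibility study assembles
from public sources: a planar road grid (standing in for an OpenStreetMap
extract), a sparser constant-speed transit overlay (standing in for a GTFS
feed), a registry of center-clustered service sites with a configurable mix
of testing/treatment/prevention flags, and square population units with
spatially heterogeneous counts of PLWH, MSM, and adults 15-64.

Everything is driven by a single integer seed; each generator derives an
independent RNG stream from (seed, salt) so stages can be re-run in any
order with identical output. Counts are drawn so that unit sums hit the
configured regional totals exactly (lognormal shares + largest-remainder
rounding for the 15-64 population; multinomial draws with center-weighted
probabilities for PLWH and MSM, redistributed deterministically so no unit
exceeds its 15-64 population).

The default service mix anchors the all-three-services fraction at ~0.545,
matching a registry in which roughly 600 of 1,100 sites offer testing,
treatment, and prevention together.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Union

import numpy as np
from shapely.geometry import Point, box
from shapely.geometry.base import BaseGeometry

from .errors import ConfigError
from .model import (
    Group,
    PopulationUnit,
    RoadEdge,
    RoadNetwork,
    Service,
    ServiceSite,
    TransitNetwork,
)

logger = logging.getLogger(__name__)

#: Default probabilities over service-flag subsets; keys are '+'-joined
#: service names. The all-three mass (0.545 ~ 600/1100) is the anchor.
DEFAULT_SERVICE_MIX: dict[str, float] = {
    "testing+treatment+prevention": 0.545,
    "testing": 0.155,
    "testing+prevention": 0.10,
    "prevention": 0.10,
    "treatment": 0.05,
    "treatment+prevention": 0.05,
}

_SALT = {"road": 11, "transit": 23, "units": 37, "sites": 53}


def parse_service_key(key: str) -> frozenset[Service]:
    try:
        return frozenset(Service(p) for p in key.split("+"))
    except ValueError as exc:
        raise ConfigError(f"bad service-mix key {key!r}: {exc}") from None


@dataclass
class ScenarioConfig:
    """Full description of a synthetic study region.

    Lengths in meters, speeds in km/h. ``road_speed_kmh`` may be a scalar or
    a (low, high) range sampled per edge. ``jitter_frac`` perturbs grid node
    coordinates by up to that fraction of the spacing (0 gives an exact
    lattice). ``clustering_sites`` / ``clustering_counts`` are
    center-attraction strengths (0 = spatially uniform).
    """

    grid_nx: int = 24
    grid_ny: int = 24
    spacing_m: float = 1200.0
    road_speed_kmh: Union[float, tuple[float, float]] = 25.0
    jitter_frac: float = 0.15
    transit_routes: int = 6
    transit_stop_spacing_m: float = 1000.0
    n_sites: int = 60
    service_mix: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SERVICE_MIX))
    n_units: int = 100
    totals: dict[str, int] = field(default_factory=lambda: {
        "pop15_64": 1_000_000, "plwh": 20_000, "msm": 50_000})
    pop_sigma: float = 0.75
    clustering_sites: float = 2.0
    clustering_counts: float = 1.5
    exclusion_zone: Optional[BaseGeometry] = None
    site_void: Optional[BaseGeometry] = None
    demand_hotspot: Optional[tuple[BaseGeometry, float]] = None
    hex_width_m: float = 500.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.grid_nx < 2 or self.grid_ny < 2:
            raise ConfigError("grid_nx and grid_ny must be >= 2")
        if not self.spacing_m > 0:
            raise ConfigError("spacing_m must be positive")
        lo, hi = self.speed_range()
        if not (lo > 0 and hi >= lo):
            raise ConfigError("road speed must be positive (and range ordered)")
        if not (0.0 <= self.jitter_frac < 0.5):
            raise ConfigError("jitter_frac must lie in [0, 0.5)")
        if self.transit_routes < 0:
            raise ConfigError("transit_routes must be >= 0")
        if not self.transit_stop_spacing_m > 0:
            raise ConfigError("transit_stop_spacing_m must be positive")
        if self.n_sites < 1:
            raise ConfigError("n_sites must be >= 1")
        if self.n_units < 1:
            raise ConfigError("n_units must be >= 1")
        if not self.hex_width_m > 0:
            raise ConfigError("hex_width_m must be positive")
        total = 0.0
        for k, p in self.service_mix.items():
            parse_service_key(k)
            if p < 0:
                raise ConfigError(f"service_mix[{k!r}] is negative")
            total += p
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(f"service_mix probabilities sum to {total}, not 1")
        for k in ("pop15_64", "plwh", "msm"):
            if k not in self.totals:
                raise ConfigError(f"totals missing {k!r}")
            if self.totals[k] < 0:
                raise ConfigError(f"totals[{k!r}] is negative")
        if self.totals["plwh"] > self.totals["pop15_64"]:
            raise ConfigError("PLWH total exceeds the 15-64 population total")
        if self.totals["msm"] > self.totals["pop15_64"]:
            raise ConfigError("MSM total exceeds the 15-64 population total")
        if self.clustering_sites < 0 or self.clustering_counts < 0:
            raise ConfigError("clustering strengths must be >= 0")

    def speed_range(self) -> tuple[float, float]:
        if isinstance(self.road_speed_kmh, (int, float)):
            return float(self.road_speed_kmh), float(self.road_speed_kmh)
        lo, hi = self.road_speed_kmh
        return float(lo), float(hi)

    @property
    def width_m(self) -> float:
        return (self.grid_nx - 1) * self.spacing_m

    @property
    def height_m(self) -> float:
        return (self.grid_ny - 1) * self.spacing_m

    def region(self) -> BaseGeometry:
        return box(0.0, 0.0, self.width_m, self.height_m)

    def rng(self, stage: str) -> np.random.Generator:
        return np.random.default_rng([self.seed % (2**31), _SALT[stage]])


def _node_id(ix: int, iy: int) -> str:
    return f"n{ix:03d}_{iy:03d}"


def gen_road_network(cfg: ScenarioConfig) -> RoadNetwork:
    """Connected planar grid road network with jittered node coordinates."""
    cfg.validate()
    rng = cfg.rng("road")
    nx_, ny_ = cfg.grid_nx, cfg.grid_ny
    s = cfg.spacing_m
    j = cfg.jitter_frac * s
    jitter = rng.uniform(-j, j, size=(nx_, ny_, 2)) if j > 0 else np.zeros((nx_, ny_, 2))
    nodes: dict[str, tuple[float, float]] = {}
    for ix in range(nx_):
        for iy in range(ny_):
            nodes[_node_id(ix, iy)] = (float(ix * s + jitter[ix, iy, 0]),
                                       float(iy * s + jitter[ix, iy, 1]))
    lo, hi = cfg.speed_range()
    pairs: list[tuple[str, str]] = []
    for ix in range(nx_):
        for iy in range(ny_):
            if ix + 1 < nx_:
                pairs.append((_node_id(ix, iy), _node_id(ix + 1, iy)))
            if iy + 1 < ny_:
                pairs.append((_node_id(ix, iy), _node_id(ix, iy + 1)))
    speeds = rng.uniform(lo, hi, size=len(pairs)) if hi > lo else np.full(len(pairs), lo)
    edges = []
    for (u, v), sp in zip(pairs, speeds):
        ux, uy = nodes[u]
        vx, vy = nodes[v]
        edges.append(RoadEdge(u=u, v=v, length_m=math.hypot(vx - ux, vy - uy),
                              speed_kmh=float(sp)))
    return RoadNetwork(nodes=nodes, edges=edges)


def gen_transit_network(road: RoadNetwork, cfg: ScenarioConfig) -> TransitNetwork:
    """Transit overlay along alternating grid rows and columns.

    Stops are placed on road nodes at roughly ``transit_stop_spacing_m``
    along each corridor; crossing routes share the stop at their common node,
    so the overlay forms a connected transfer graph. Zero routes yields an
    empty (drive-only) network with a warning.
    """
    cfg.validate()
    if cfg.transit_routes == 0:
        logger.warning("transit_routes = 0: generating an empty transit network "
                       "(drive-only scenario)")
        return TransitNetwork(stops={}, links=[])
    nx_, ny_ = cfg.grid_nx, cfg.grid_ny
    corridors: list[list[str]] = []
    n_rows = (cfg.transit_routes + 1) // 2
    n_cols = cfg.transit_routes // 2
    row_iys = [((k + 1) * ny_) // (n_rows + 1) for k in range(n_rows)]
    col_ixs = [((k + 1) * nx_) // (n_cols + 1) for k in range(n_cols)]
    for iy in row_iys:
        corridors.append([_node_id(ix, iy) for ix in range(nx_)])
    for ix in col_ixs:
        corridors.append([_node_id(ix, iy) for iy in range(ny_)])
    # transfer stops where corridors cross keep the stop graph connected
    crossings = {_node_id(ix, iy) for ix in col_ixs for iy in row_iys}

    stops: dict[str, tuple[float, float]] = {}
    links: dict[frozenset[str], float] = {}
    routes: list[tuple[str, list[str]]] = []
    for r, corridor in enumerate(corridors):
        seq: list[str] = []
        acc = 0.0
        prev = None
        for node in corridor:
            if prev is not None:
                px, py = road.nodes[prev]
                qx, qy = road.nodes[node]
                acc += math.hypot(qx - px, qy - py)
            if (prev is None or acc >= cfg.transit_stop_spacing_m
                    or node == corridor[-1] or node in crossings):
                stop_id = f"s_{node}"
                stops[stop_id] = road.nodes[node]
                if seq and seq[-1] != stop_id:
                    a, b = seq[-1], stop_id
                    ax, ay = stops[a]
                    bx, by = stops[b]
                    links.setdefault(frozenset((a, b)), math.hypot(bx - ax, by - ay))
                if not seq or seq[-1] != stop_id:
                    seq.append(stop_id)
                acc = 0.0
            prev = node
        routes.append((f"r{r:02d}", seq))
    link_list = sorted(
        (tuple(sorted(k)) + (v,) for k, v in links.items()))
    return TransitNetwork(stops=stops,
                          links=[(u, v, l) for u, v, l in link_list],
                          routes=routes)


def _largest_remainder(shares: np.ndarray, total: int) -> np.ndarray:
    """Integer apportionment of ``total`` by shares, exact by construction."""
    quotas = shares / shares.sum() * total
    base = np.floor(quotas).astype(np.int64)
    short = total - int(base.sum())
    if short > 0:
        remainders = quotas - base
        # stable order: largest remainder first, index breaks ties
        order = np.lexsort((np.arange(len(base)), -remainders))
        base[order[:short]] += 1
    return base


def _center_weights(centers: np.ndarray, cfg: ScenarioConfig,
                    strength: float) -> np.ndarray:
    cx, cy = cfg.width_m / 2.0, cfg.height_m / 2.0
    d = np.hypot(centers[:, 0] - cx, centers[:, 1] - cy)
    dmax = math.hypot(cx, cy)
    return np.exp(-strength * d / dmax)


def _capped_multinomial(rng: np.random.Generator, total: int, probs: np.ndarray,
                        caps: np.ndarray) -> np.ndarray:
    """Multinomial draw with per-cell caps; overflow moved deterministically
    to the highest-probability cells with remaining slack."""
    if total > int(caps.sum()):
        raise ConfigError("group total exceeds the summed per-unit capacity")
    counts = rng.multinomial(total, probs).astype(np.int64)
    overflow = counts - caps
    excess = int(np.clip(overflow, 0, None).sum())
    counts = np.minimum(counts, caps)
    if excess:
        order = np.lexsort((np.arange(len(probs)), -probs))
        for i in order:
            if excess == 0:
                break
            slack = int(caps[i] - counts[i])
            if slack > 0:
                take = min(slack, excess)
                counts[i] += take
                excess -= take
    return counts


def gen_population_units(cfg: ScenarioConfig) -> list[PopulationUnit]:
    """Square population tiles with counts summing exactly to the totals.

    15-64 population follows a lognormal share model; PLWH and MSM are
    multinomial with center-weighted probabilities (optionally boosted inside
    ``demand_hotspot``), capped per unit at the 15-64 count.
    """
    cfg.validate()
    rng = cfg.rng("units")
    ux = max(1, int(round(math.sqrt(cfg.n_units))))
    uy = int(math.ceil(cfg.n_units / ux))
    n = ux * uy
    if n != cfg.n_units:
        logger.info("n_units %d realized as full %dx%d tiling (%d units)",
                    cfg.n_units, ux, uy, n)
    tw, th = cfg.width_m / ux, cfg.height_m / uy
    geoms, centers, ids = [], [], []
    for i in range(ux):
        for k in range(uy):
            geoms.append(box(i * tw, k * th, (i + 1) * tw, (k + 1) * th))
            centers.append(((i + 0.5) * tw, (k + 0.5) * th))
            ids.append(f"u{i:02d}_{k:02d}")
    centers = np.array(centers)

    shares = rng.lognormal(mean=0.0, sigma=cfg.pop_sigma, size=n)
    hot_mask = np.zeros(n, dtype=bool)
    boost = 1.0
    if cfg.demand_hotspot is not None:
        hot_poly, boost = cfg.demand_hotspot
        hot_mask = np.array([hot_poly.contains(Point(c)) for c in centers])
        shares = np.where(hot_mask, shares * boost, shares)
    pop = _largest_remainder(shares, cfg.totals["pop15_64"])

    # center-weighted intensity; uniform across units when clustering is 0
    w = _center_weights(centers, cfg, cfg.clustering_counts)
    if cfg.demand_hotspot is not None:
        w = np.where(hot_mask, w * boost, w)
    probs = w / w.sum()
    plwh = _capped_multinomial(rng, cfg.totals["plwh"], probs, pop)
    msm = _capped_multinomial(rng, cfg.totals["msm"], probs, pop)

    cx, cy = cfg.width_m / 2.0, cfg.height_m / 2.0
    dmax = math.hypot(cx, cy)
    units = []
    for idx in range(n):
        d = math.hypot(centers[idx, 0] - cx, centers[idx, 1] - cy)
        units.append(PopulationUnit(
            unit_id=ids[idx], geometry=geoms[idx],
            counts={Group.AGE15_64: int(pop[idx]), Group.PLWH: int(plwh[idx]),
                    Group.MSM: int(msm[idx])},
            male_pop=int(pop[idx]) // 2,
            urbanicity="urban" if d <= 0.5 * dmax else "rural",
        ))
    return units


def gen_service_sites(cfg: ScenarioConfig) -> list[ServiceSite]:
    """Center-attracted service sites with flags drawn from the service mix.

    Sites are rejection-sampled: a uniform candidate is kept with probability
    exp(-clustering * d/dmax) (always, when clustering is 0) and never placed
    inside the exclusion zone or the planted site void.
    """
    cfg.validate()
    rng = cfg.rng("sites")
    W, H = cfg.width_m, cfg.height_m
    cx, cy = W / 2.0, H / 2.0
    dmax = math.hypot(cx, cy)
    keys = sorted(cfg.service_mix)
    probs = np.array([cfg.service_mix[k] for k in keys])
    flag_sets = [parse_service_key(k) for k in keys]
    sites: list[ServiceSite] = []
    i = 0
    while len(sites) < cfg.n_sites:
        x = float(rng.uniform(0.0, W))
        y = float(rng.uniform(0.0, H))
        if cfg.clustering_sites > 0:
            d = math.hypot(x - cx, y - cy)
            if rng.uniform() > math.exp(-cfg.clustering_sites * d / dmax):
                continue
        p = Point(x, y)
        if cfg.exclusion_zone is not None and cfg.exclusion_zone.contains(p):
            continue
        if cfg.site_void is not None and cfg.site_void.contains(p):
            continue
        choice = int(rng.choice(len(keys), p=probs))
        sites.append(ServiceSite(site_id=f"site{i:04d}", x=x, y=y,
                                 services=flag_sets[choice]))
        i += 1
    return sites


@dataclass
class Scenario:
    """A full synthetic input bundle."""

    config: ScenarioConfig
    road: RoadNetwork
    transit: Optional[TransitNetwork]
    sites: list[ServiceSite]
    units: list[PopulationUnit]

    @property
    def region(self) -> BaseGeometry:
        return self.config.region()


PRESETS = ("city", "state", "underserved_demo")


def _preset_config(preset: str, seed: int) -> ScenarioConfig:
    if preset == "city":
        return ScenarioConfig(seed=seed)
    if preset == "state":
        return ScenarioConfig(
            grid_nx=15, grid_ny=15, spacing_m=5000.0, road_speed_kmh=(60.0, 100.0),
            transit_routes=0, n_sites=60, n_units=100,
            totals={"pop15_64": 800_000, "plwh": 8_000, "msm": 20_000},
            clustering_sites=1.0, clustering_counts=1.0,
            hex_width_m=5000.0, seed=seed)
    if preset == "underserved_demo":
        cfg = ScenarioConfig(seed=seed)
        quadrant = box(0.0, 0.0, cfg.width_m / 2.0, cfg.height_m / 2.0)
        cfg.site_void = quadrant
        cfg.demand_hotspot = (quadrant, 3.0)
        return cfg
    raise ConfigError(f"unknown preset {preset!r}; available presets: "
                      + ", ".join(PRESETS))


def gen_scenario(preset: str, seed: int = 0) -> Scenario:
    """Generate a complete scenario from a named preset.

    Presets: "city" (grid with transit overlay, 500 m hexagons), "state"
    (larger spacing, drive-only, 5 km hexagons), "underserved_demo" (city
    layout with a planted high-demand, zero-site quadrant).
    """
    cfg = _preset_config(preset, seed)
    road = gen_road_network(cfg)
    transit = gen_transit_network(road, cfg) if cfg.transit_routes > 0 else None
    return Scenario(config=cfg, road=road, transit=transit,
                    sites=gen_service_sites(cfg), units=gen_population_units(cfg))
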