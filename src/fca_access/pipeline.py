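"""End-to-end orchestration: inputs -> catchments -> surfaces -> statistics.

A run is described by a single YAML config (or a RunConfig object): either a
synthetic preset + seed or paths to user-supplied inputs, the travel modes
to analyze, the zone scheme, the E2SFCA variant, and the hexagon width. The
run writes one GeoJSON surface per (service, group, mode), a JSON statistics
report, and a provenance sidecar echoing the config. Each stage is also
exposed standalone (synth / travel / e2sfca / stats) over serialized
intermediates; composing the stages reproduces the monolithic run
byte-for-byte.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import Optional, Sequence

from shapely.geometry import box, shape, mapping

from . import __version__
from .errors import ConfigError, DataError
from .e2sfca import compute_zone_sets, hex_grid, normalize, surface, zones_of_points
from .io import (
    load_yaml,
    read_gtfs_subset,
    read_population,
    read_road_network,
    read_sites,
    read_surface,
    read_zone_sets,
    save_yaml,
    write_gtfs_subset,
    write_population,
    write_report,
    write_road_network,
    write_sites,
    write_surface,
    write_zone_sets,
)
from .model import (
    Group,
    HexGrid,
    PopulationUnit,
    RoadNetwork,
    Service,
    ServiceSite,
    TransitNetwork,
    TravelZoneScheme,
    service_group_pairs,
)
from .stats import compare_surfaces
from .synthetic import PRESETS, Scenario, gen_scenario

logger = logging.getLogger(__name__)

SCHEMA_VERSION = 1
MODES = ("drive", "transit")

_KNOWN_KEYS = {
    "schema_version", "synthetic", "inputs", "modes", "variant", "scheme",
    "hex_width_m", "transit_speed_mph", "exclusion", "output_dir", "log_level",
}
_KNOWN_SYNTH_KEYS = {"preset", "seed"}
_KNOWN_INPUT_KEYS = {"sites", "units", "road_nodes", "road_edges", "gtfs_dir",
                     "region"}


@dataclass
class RunConfig:
    """Validated run description; see module docstring for semantics."""

    output_dir: str
    preset: Optional[str] = None
    seed: int = 0
    input_paths: dict[str, str] = field(default_factory=dict)
    modes: tuple[str, ...] = ("drive",)
    variant: str = "as_printed"
    scheme: TravelZoneScheme = field(default_factory=TravelZoneScheme)
    hex_width_m: Optional[float] = None
    transit_speed_mph: float = 10.0
    exclusion_path: Optional[str] = None
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if (self.preset is None) == (not self.input_paths):
            raise ConfigError("exactly one of synthetic preset or input paths "
                              "must be given")
        if self.preset is not None and self.preset not in PRESETS:
            raise ConfigError(f"unknown preset {self.preset!r}; available: "
                              + ", ".join(PRESETS))
        for m in self.modes:
            if m not in MODES:
                raise ConfigError(f"unknown mode {m!r}; expected drive/transit")
        if not self.modes:
            raise ConfigError("at least one travel mode is required")
        if self.input_paths:
            unknown = set(self.input_paths) - _KNOWN_INPUT_KEYS
            if unknown:
                raise ConfigError(f"unknown input keys: {sorted(unknown)}")
            for key in ("sites", "units", "road_nodes", "road_edges"):
                if key not in self.input_paths:
                    raise ConfigError(f"inputs missing required path {key!r}")
                if not os.path.exists(self.input_paths[key]):
                    raise ConfigError(
                        f"input path does not exist: {self.input_paths[key]!r}")
            if "transit" in self.modes and "gtfs_dir" not in self.input_paths:
                raise ConfigError("transit mode requires inputs.gtfs_dir")
        if self.exclusion_path is not None and not os.path.exists(self.exclusion_path):
            raise ConfigError(f"exclusion path does not exist: {self.exclusion_path!r}")

    @classmethod
    def from_dict(cls, data: dict, base_dir: str = ".") -> "RunConfig":
        unknown = set(data) - _KNOWN_KEYS
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if int(data.get("schema_version", SCHEMA_VERSION)) != SCHEMA_VERSION:
            raise ConfigError("unsupported schema_version")

        def rel(p):
            return p if os.path.isabs(p) else os.path.join(base_dir, p)

        synth = data.get("synthetic") or {}
        if set(synth) - _KNOWN_SYNTH_KEYS:
            raise ConfigError(f"unknown synthetic keys: "
                              f"{sorted(set(synth) - _KNOWN_SYNTH_KEYS)}")
        inputs = {k: rel(v) for k, v in (data.get("inputs") or {}).items()}
        scheme_cfg = data.get("scheme") or {}
        scheme = TravelZoneScheme(
            breaks_min=tuple(scheme_cfg.get("breaks_min", (10.0, 20.0, 30.0))),
            weights=tuple(scheme_cfg.get("weights", (1.0, 0.68, 0.22))))
        return cls(
            output_dir=rel(data.get("output_dir", "out")),
            preset=synth.get("preset"),
            seed=int(synth.get("seed", 0)),
            input_paths=inputs,
            modes=tuple(data.get("modes", ("drive",))),
            variant=data.get("variant", "as_printed"),
            scheme=scheme,
            hex_width_m=data.get("hex_width_m"),
            transit_speed_mph=float(data.get("transit_speed_mph", 10.0)),
            exclusion_path=(rel(data["exclusion"])
                            if data.get("exclusion") else None),
            log_level=data.get("log_level", "INFO"),
        )

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        return cls.from_dict(load_yaml(path), base_dir=os.path.dirname(path) or ".")

    def echo(self) -> dict:
        return {
            "schema_version": SCHEMA_VERSION,
            "synthetic": ({"preset": self.preset, "seed": self.seed}
                          if self.preset else None),
            "inputs": self.input_paths or None,
            "modes": list(self.modes),
            "variant": self.variant,
            "scheme": {"breaks_min": list(self.scheme.breaks_min),
                       "weights": list(self.scheme.weights)},
            "hex_width_m": self.hex_width_m,
            "transit_speed_mph": self.transit_speed_mph,
            "exclusion": self.exclusion_path,
            "output_dir": self.output_dir,
            "version": __version__,
        }


@dataclass
class RunInputs:
    sites: list[ServiceSite]
    units: list[PopulationUnit]
    road: RoadNetwork
    transit: Optional[TransitNetwork]
    region: object  # shapely geometry
    hex_width_m: float


def _load_inputs(config: RunConfig) -> RunInputs:
    if config.preset is not None:
        sc: Scenario = gen_scenario(config.preset, config.seed)
        return RunInputs(sites=sc.sites, units=sc.units, road=sc.road,
                         transit=sc.transit, region=sc.region,
                         hex_width_m=config.hex_width_m or sc.config.hex_width_m)
    p = config.input_paths
    sites = read_sites(p["sites"])
    units = read_population(p["units"])
    road = read_road_network(p["road_nodes"], p["road_edges"])
    transit = None
    if "gtfs_dir" in p:
        transit = read_gtfs_subset(p["gtfs_dir"],
                                   constant_speed_mph=config.transit_speed_mph)
    if "region" in p:
        region = _read_region(p["region"])
    else:
        ids, coords = road.node_array()
        region = box(coords[:, 0].min(), coords[:, 1].min(),
                     coords[:, 0].max(), coords[:, 1].max())
    if config.hex_width_m is None:
        raise ConfigError("hex_width_m is required when running on user inputs")
    return RunInputs(sites=sites, units=units, road=road, transit=transit,
                     region=region, hex_width_m=config.hex_width_m)


def _read_region(path: str):
    import json
    with open(path, encoding="utf-8") as fh:
        data = json.load(fh)
    if data.get("type") == "FeatureCollection":
        geoms = [shape(f["geometry"]) for f in data["features"]]
        from shapely.ops import unary_union
        return unary_union(geoms)
    if data.get("type") == "Feature":
        return shape(data["geometry"])
    return shape(data)


def _surface_filename(service: Service, group: Group, mode: str) -> str:
    return f"surface_{service.value}_{group.value}_{mode}.geojson"


def compute_surfaces(inputs: RunInputs, config: RunConfig,
                     grid: Optional[HexGrid] = None) -> dict:
    """All (service, group, mode) surfaces on a shared grid."""
    exclusion = (_read_region(config.exclusion_path)
                 if config.exclusion_path else None)
    if grid is None:
        grid = hex_grid(inputs.region, inputs.hex_width_m, exclusion)
    surfaces = {}
    for mode in config.modes:
        if mode == "transit" and (inputs.transit is None or inputs.transit.is_empty):
            raise DataError("transit mode requested but no transit network "
                            "is available")
        zone_sets = compute_zone_sets(inputs.sites, mode, inputs.road,
                                      inputs.transit, config.scheme)
        pts = grid.points()
        zone_cache = {sid: zones_of_points(pts, zs)
                      for sid, zs in zone_sets.items()}
        for service, group in service_group_pairs():
            surf = surface(service, group, inputs.sites, inputs.units, grid,
                           config.scheme, mode=mode, variant=config.variant,
                           zone_sets=zone_sets, zone_cache=zone_cache)
            surfaces[(service, group, mode)] = normalize(surf)
    return surfaces


def run(config: RunConfig) -> dict:
    """Execute the full workflow; returns {'surfaces', 'report', 'paths'}."""
    os.makedirs(config.output_dir, exist_ok=True)
    logger.info("stage=load preset=%s", config.preset or "files")
    inputs = _load_inputs(config)
    logger.info("stage=surfaces modes=%s sites=%d units=%d",
                ",".join(config.modes), len(inputs.sites), len(inputs.units))
    surfaces = compute_surfaces(inputs, config)
    paths = {}
    for (service, group, mode), surf in surfaces.items():
        fn = os.path.join(config.output_dir, _surface_filename(service, group, mode))
        write_surface(surf, fn)
        paths[f"{service.value}_{group.value}_{mode}"] = fn
    logger.info("stage=stats surfaces=%d", len(surfaces))
    report = compare_surfaces(surfaces)
    report_path = os.path.join(config.output_dir, "report.json")
    write_report(report, report_path)
    provenance_path = os.path.join(config.output_dir, "provenance.json")
    write_report(config.echo(), provenance_path)
    return {"surfaces": surfaces, "report": report,
            "paths": dict(paths, report=report_path, provenance=provenance_path)}


# ------------------------------------------------------- standalone stages

def stage_synth(preset: str, seed: int, out_dir: str) -> dict:
    """Generate a scenario and serialize every input the later stages read."""
    os.makedirs(out_dir, exist_ok=True)
    sc = gen_scenario(preset, seed)
    paths = {
        "sites": os.path.join(out_dir, "sites.csv"),
        "units": os.path.join(out_dir, "units.geojson"),
        "road_nodes": os.path.join(out_dir, "road_nodes.csv"),
        "road_edges": os.path.join(out_dir, "road_edges.csv"),
    }
    write_sites(sc.sites, paths["sites"])
    write_population(sc.units, paths["units"])
    write_road_network(sc.road, paths["road_nodes"], paths["road_edges"])
    if sc.transit is not None:
        paths["gtfs_dir"] = os.path.join(out_dir, "gtfs")
        write_gtfs_subset(sc.transit, paths["gtfs_dir"])
    minx, miny, maxx, maxy = sc.region.bounds
    scen_meta = {"preset": preset, "seed": seed,
                 "hex_width_m": sc.config.hex_width_m,
                 "region_bounds": [minx, miny, maxx, maxy]}
    save_yaml(scen_meta, os.path.join(out_dir, "scenario.yaml"))
    return paths


def stage_travel(in_dir: str, out_dir: str, modes: Sequence[str],
                 scheme: TravelZoneScheme,
                 transit_speed_mph: float = 10.0) -> dict:
    """Compute catchment zone sets from serialized inputs; write one zone
    GeoJSON per mode."""
    os.makedirs(out_dir, exist_ok=True)
    sites = read_sites(os.path.join(in_dir, "sites.csv"))
    road = read_road_network(os.path.join(in_dir, "road_nodes.csv"),
                             os.path.join(in_dir, "road_edges.csv"))
    transit = None
    gtfs = os.path.join(in_dir, "gtfs")
    if os.path.isdir(gtfs):
        transit = read_gtfs_subset(gtfs, constant_speed_mph=transit_speed_mph)
    paths = {}
    for mode in modes:
        zone_sets = compute_zone_sets(sites, mode, road, transit, scheme)
        paths[mode] = os.path.join(out_dir, f"zones_{mode}.geojson")
        write_zone_sets(zone_sets, paths[mode])
    return paths


def stage_e2sfca(in_dir: str, zones_dir: str, out_dir: str,
                 modes: Sequence[str], variant: str = "as_printed") -> dict:
    """Compute and write surfaces from serialized inputs plus zone files."""
    os.makedirs(out_dir, exist_ok=True)
    sites = read_sites(os.path.join(in_dir, "sites.csv"))
    units = read_population(os.path.join(in_dir, "units.geojson"))
    meta = load_yaml(os.path.join(in_dir, "scenario.yaml"))
    minx, miny, maxx, maxy = meta["region_bounds"]
    grid = hex_grid(box(minx, miny, maxx, maxy), float(meta["hex_width_m"]))
    paths = {}
    for mode in modes:
        zone_sets = read_zone_sets(os.path.join(zones_dir, f"zones_{mode}.geojson"))
        scheme = next(iter(zone_sets.values())).scheme
        pts = grid.points()
        zone_cache = {sid: zones_of_points(pts, zs)
                      for sid, zs in zone_sets.items()}
        for service, group in service_group_pairs():
            surf = surface(service, group, sites, units, grid, scheme,
                           mode=mode, variant=variant, zone_sets=zone_sets,
                           zone_cache=zone_cache)
            normalize(surf)
            fn = os.path.join(out_dir, _surface_filename(service, group, mode))
            write_surface(surf, fn)
            paths[f"{service.value}_{group.value}_{mode}"] = fn
    return paths


def stage_stats(surface_paths: Sequence[str], out_path: str) -> dict:
    """Statistics report from serialized surfaces."""
    surfaces = {}
    for p in surface_paths:
        surf = read_surface(p)
        meta = surf.metadata
        key = (Service(meta["service"]), Group(meta["group"]), meta["mode"])
        surfaces[key] = surf
    report = compare_surfaces(surfaces)
    write_report(report, out_path)
    return report
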