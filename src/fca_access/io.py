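"""Readers and writers for every external format the pipeline touches.

Formats: service-site CSV, population-unit GeoJSON, road node/edge CSV,
a GTFS text subset (stops.txt, routes.txt, trips.txt, stop_times.txt),
catchment-zone GeoJSON, accessibility-surface GeoJSON, and JSON statistics
reports. All text I/O is UTF-8; CSV is comma-separated with a required
header row. Coordinates are planar meters; GTFS stops given as lat/lon are
converted with an equirectangular projection about the feed's mean latitude.

Readers validate strictly and fail loudly: missing columns, dangling
references, duplicate ids, negative or fractional counts are all errors
naming the offending record. write-then-read is the identity on valid data
(floats round-trip exactly through repr-based formatting).
"""

from __future__ import annotations

import csv
import json
import math
import os
from typing import Iterable, Optional, Sequence

import numpy as np
import yaml
from shapely.geometry import Point, mapping, shape
from shapely.geometry.base import BaseGeometry

from .errors import DataError, SchemaError, ValidationError
from .model import (
    AccessibilitySurface,
    CatchmentZoneSet,
    Group,
    HexCell,
    HexGrid,
    PopulationUnit,
    RoadEdge,
    RoadNetwork,
    Service,
    ServiceSite,
    TransitNetwork,
    TravelZoneScheme,
)

EARTH_RADIUS_M = 6_371_000.0

_SITE_COLUMNS = ("site_id", "x", "y", "testing", "treatment", "prevention")
_COUNT_KEYS = {g.value: g for g in Group}
_OPTIONAL_UNIT_FIELDS = ("male_pop", "households", "ssm_households", "urbanicity")


def _require_columns(have: Sequence[str], want: Sequence[str], what: str) -> None:
    missing = [c for c in want if c not in have]
    if missing:
        raise SchemaError(f"{what}: missing column(s) {', '.join(missing)}")


def _read_csv_rows(path: str, required: Sequence[str], what: str) -> list[dict]:
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise SchemaError(f"{what}: file {path!r} is empty (no header)")
        _require_columns(reader.fieldnames, required, what)
        return list(reader)


def _parse_flag(raw: str, column: str, row_id: str) -> bool:
    v = raw.strip()
    if v in ("0", "1"):
        return v == "1"
    raise ValidationError(f"row {row_id!r}: column {column!r} must be 0 or 1, got {raw!r}")


def _parse_int(raw, what: str):
    """Strict integer parse: fractional values are rejected, not rounded."""
    try:
        f = float(raw)
    except (TypeError, ValueError):
        raise ValidationError(f"{what}: not a number: {raw!r}") from None
    if not math.isfinite(f) or f != int(f):
        raise ValidationError(f"{what}: expected an integer, got {raw!r}")
    return int(f)


# ---------------------------------------------------------------- sites CSV

def read_sites(path: str) -> list[ServiceSite]:
    """Read a service-site registry CSV (site_id, x, y, testing, treatment,
    prevention, optional capacity)."""
    rows = _read_csv_rows(path, _SITE_COLUMNS, "sites CSV")
    sites: list[ServiceSite] = []
    seen: set[str] = set()
    for row in rows:
        sid = row["site_id"]
        if sid in seen:
            raise ValidationError(f"duplicate site_id {sid!r}")
        seen.add(sid)
        services = frozenset(
            s for s in Service if _parse_flag(row[s.value], s.value, sid))
        if not services:
            raise ValidationError(f"site {sid!r} has all-zero service flags")
        cap = row.get("capacity")
        capacity = float(cap) if cap not in (None, "") else 1.0
        sites.append(ServiceSite(site_id=sid, x=float(row["x"]), y=float(row["y"]),
                                 services=services, capacity=capacity))
    return sites


def write_sites(sites: Sequence[ServiceSite], path: str) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(_SITE_COLUMNS + ("capacity",))
        for s in sites:
            w.writerow([s.site_id, repr(float(s.x)), repr(float(s.y))]
                       + [int(sv in s.services) for sv in Service]
                       + [repr(float(s.capacity))])


# ------------------------------------------------------- population GeoJSON

def read_population(path: str) -> list[PopulationUnit]:
    """Read population units from a GeoJSON FeatureCollection.

    Properties: unit_id, per-group counts (plwh, msm, pop15_64; missing
    counts are simply absent), optional male_pop/households/ssm_households/
    urbanicity. Point features are accepted (a point is its own centroid).
    """
    with open(path, encoding="utf-8") as fh:
        data = json.load(fh)
    if data.get("type") != "FeatureCollection":
        raise SchemaError(f"{path!r}: expected a GeoJSON FeatureCollection")
    units: list[PopulationUnit] = []
    for i, feat in enumerate(data.get("features", [])):
        props = feat.get("properties") or {}
        uid = str(props.get("unit_id", f"feature{i}"))
        try:
            geom = shape(feat["geometry"])
        except (KeyError, TypeError, AttributeError) as exc:
            raise DataError(f"unit {uid!r}: invalid geometry ({exc})") from None
        if geom.is_empty or not np.all(np.isfinite(np.asarray(geom.bounds))):
            raise DataError(f"unit {uid!r}: empty or non-finite geometry")
        counts = {}
        for key, group in _COUNT_KEYS.items():
            if key in props and props[key] is not None:
                c = _parse_int(props[key], f"unit {uid!r}: count {key!r}")
                if c < 0:
                    raise ValidationError(f"unit {uid!r}: negative count for {key!r}")
                counts[group] = c
        extra = {}
        for f_ in _OPTIONAL_UNIT_FIELDS:
            if f_ in props and props[f_] is not None:
                extra[f_] = (props[f_] if f_ == "urbanicity"
                             else _parse_int(props[f_], f"unit {uid!r}: {f_}"))
        units.append(PopulationUnit(unit_id=uid, geometry=geom, counts=counts, **extra))
    return units


def write_population(units: Sequence[PopulationUnit], path: str) -> None:
    feats = []
    for u in units:
        props = {"unit_id": u.unit_id}
        props.update({g.value: int(c) for g, c in u.counts.items()})
        for f_ in _OPTIONAL_UNIT_FIELDS:
            v = getattr(u, f_)
            if v is not None:
                props[f_] = v
        feats.append({"type": "Feature", "geometry": mapping(u.geometry),
                      "properties": props})
    _dump_json({"type": "FeatureCollection", "features": feats}, path)


# ------------------------------------------------------------ road network

def read_road_network(nodes_path: str, edges_path: str) -> RoadNetwork:
    """Road network from a node CSV (node_id, x, y) and an edge-list CSV
    (u, v, length_m, speed_kmh)."""
    node_rows = _read_csv_rows(nodes_path, ("node_id", "x", "y"), "road nodes CSV")
    nodes: dict[str, tuple[float, float]] = {}
    for row in node_rows:
        nid = row["node_id"]
        if nid in nodes:
            raise ValidationError(f"duplicate node_id {nid!r}")
        nodes[nid] = (float(row["x"]), float(row["y"]))
    edge_rows = _read_csv_rows(edges_path, ("u", "v", "length_m", "speed_kmh"),
                               "road edges CSV")
    edges = []
    for row in edge_rows:
        if row["u"] not in nodes:
            raise DataError(f"edge references missing node {row['u']!r}")
        if row["v"] not in nodes:
            raise DataError(f"edge references missing node {row['v']!r}")
        edges.append(RoadEdge(u=row["u"], v=row["v"],
                              length_m=float(row["length_m"]),
                              speed_kmh=float(row["speed_kmh"])))
    return RoadNetwork(nodes=nodes, edges=edges)


def write_road_network(road: RoadNetwork, nodes_path: str, edges_path: str) -> None:
    with open(nodes_path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["node_id", "x", "y"])
        for nid in sorted(road.nodes):
            x, y = road.nodes[nid]
            w.writerow([nid, repr(float(x)), repr(float(y))])
    with open(edges_path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["u", "v", "length_m", "speed_kmh"])
        for e in road.edges:
            w.writerow([e.u, e.v, repr(float(e.length_m)), repr(float(e.speed_kmh))])


# ------------------------------------------------------------- GTFS subset

def read_gtfs_subset(directory: str,
                     constant_speed_mph: float = 10.0) -> TransitNetwork:
    """Build a transit stop graph from a GTFS text subset.

    Only stops.txt, trips.txt, and stop_times.txt are consulted; one
    undirected, deduplicated link joins each pair of consecutive stops in a
    trip, with length equal to the planar distance between the stops.
    Timetable times are ignored: travel time comes from the constant speed.
    """
    stops_path = os.path.join(directory, "stops.txt")
    rows = _read_csv_rows(stops_path, ("stop_id",), "stops.txt")
    fieldnames = rows[0].keys() if rows else ()
    if rows and {"x", "y"} <= set(fieldnames):
        stops = {r["stop_id"]: (float(r["x"]), float(r["y"])) for r in rows}
    elif rows and {"stop_lat", "stop_lon"} <= set(fieldnames):
        lat0 = math.radians(
            sum(float(r["stop_lat"]) for r in rows) / len(rows))
        stops = {}
        for r in rows:
            lam = math.radians(float(r["stop_lon"]))
            phi = math.radians(float(r["stop_lat"]))
            stops[r["stop_id"]] = (EARTH_RADIUS_M * lam * math.cos(lat0),
                                   EARTH_RADIUS_M * phi)
    elif not rows:
        stops = {}
    else:
        raise SchemaError("stops.txt: need either x/y or stop_lat/stop_lon columns")
    if len(stops) != len(rows):
        raise ValidationError("stops.txt: duplicate stop_id")

    st_path = os.path.join(directory, "stop_times.txt")
    st_rows = _read_csv_rows(st_path, ("trip_id", "stop_id", "stop_sequence"),
                             "stop_times.txt")
    trips_path = os.path.join(directory, "trips.txt")
    trip_rows = _read_csv_rows(trips_path, ("trip_id",), "trips.txt")
    trip_route = {r["trip_id"]: r.get("route_id", r["trip_id"]) for r in trip_rows}

    by_trip: dict[str, list[tuple[int, str]]] = {}
    for r in st_rows:
        sid = r["stop_id"]
        if sid not in stops:
            raise DataError(f"stop_times.txt references unknown stop {sid!r}")
        by_trip.setdefault(r["trip_id"], []).append((int(r["stop_sequence"]), sid))
    links: dict[frozenset[str], float] = {}
    routes: dict[str, list[str]] = {}
    for trip_id in sorted(by_trip):
        seq = [sid for _, sid in sorted(by_trip[trip_id])]
        routes.setdefault(trip_route.get(trip_id, trip_id), seq)
        for a, b in zip(seq, seq[1:]):
            if a == b:
                continue
            ax, ay = stops[a]
            bx, by = stops[b]
            links.setdefault(frozenset((a, b)), math.hypot(bx - ax, by - ay))
    link_list = sorted(tuple(sorted(k)) + (v,) for k, v in links.items())
    return TransitNetwork(stops=stops,
                          links=[(u, v, l) for u, v, l in link_list],
                          constant_speed_mph=constant_speed_mph,
                          routes=sorted(routes.items()))


def write_gtfs_subset(transit: TransitNetwork, directory: str) -> None:
    """Write the GTFS text subset (stops/routes/trips/stop_times) with planar
    x/y stop coordinates. One trip per route; if no routes are recorded, one
    two-stop trip per link."""
    os.makedirs(directory, exist_ok=True)
    with open(os.path.join(directory, "stops.txt"), "w", newline="",
              encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["stop_id", "x", "y"])
        for sid in sorted(transit.stops):
            x, y = transit.stops[sid]
            w.writerow([sid, repr(float(x)), repr(float(y))])
    routes = transit.routes or [
        (f"link{i:04d}", [u, v]) for i, (u, v, _) in enumerate(transit.links)]
    with open(os.path.join(directory, "routes.txt"), "w", newline="",
              encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["route_id", "route_type"])
        for rid, _ in routes:
            w.writerow([rid, 3])
    with open(os.path.join(directory, "trips.txt"), "w", newline="",
              encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["route_id", "trip_id"])
        for rid, _ in routes:
            w.writerow([rid, f"{rid}_t0"])
    with open(os.path.join(directory, "stop_times.txt"), "w", newline="",
              encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["trip_id", "stop_id", "stop_sequence"])
        for rid, seq in routes:
            for i, sid in enumerate(seq):
                w.writerow([f"{rid}_t0", sid, i])


# --------------------------------------------------- zones, surface, report

def write_zone_sets(zone_sets: dict[str, CatchmentZoneSet], path: str) -> None:
    """Catchment hulls as a GeoJSON FeatureCollection (site_id, zone index,
    weight per feature) for inspection and stage chaining."""
    feats = []
    scheme = None
    for sid in sorted(zone_sets):
        zs = zone_sets[sid]
        scheme = zs.scheme
        for r, hull in enumerate(zs.hulls, start=1):
            feats.append({"type": "Feature", "geometry": mapping(hull),
                          "properties": {"site_id": sid, "zone": r,
                                         "weight": zs.scheme.weight_of_zone(r)}})
    doc = {"type": "FeatureCollection", "features": feats}
    if scheme is not None:
        doc["metadata"] = {"breaks_min": list(scheme.breaks_min),
                           "weights": list(scheme.weights)}
    _dump_json(doc, path)


def read_zone_sets(path: str) -> dict[str, CatchmentZoneSet]:
    with open(path, encoding="utf-8") as fh:
        data = json.load(fh)
    meta = data.get("metadata")
    if meta is None:
        raise SchemaError(f"{path!r}: zone file lacks scheme metadata")
    scheme = TravelZoneScheme(breaks_min=tuple(meta["breaks_min"]),
                              weights=tuple(meta["weights"]))
    hulls_by_site: dict[str, dict[int, BaseGeometry]] = {}
    for feat in data["features"]:
        p = feat["properties"]
        hulls_by_site.setdefault(p["site_id"], {})[int(p["zone"])] = shape(
            feat["geometry"])
    out = {}
    for sid, by_zone in hulls_by_site.items():
        hulls = [by_zone[r] for r in sorted(by_zone)]
        rings = [hulls[0]] + [o.difference(i) for i, o in zip(hulls, hulls[1:])]
        out[sid] = CatchmentZoneSet(site_id=sid, hulls=hulls, rings=rings,
                                    scheme=scheme)
    return out


def write_surface(surf: AccessibilitySurface, path: str) -> None:
    """Accessibility surface as GeoJSON hexagon features with cell_id, A,
    and A_normalized properties; run metadata as a foreign member."""
    feats = []
    norm = surf.A_normalized
    for i, cell in enumerate(surf.grid.cells):
        props = {"cell_id": cell.cell_id, "A": float(surf.A[i]),
                 "A_normalized": (float(norm[i]) if norm is not None else None)}
        feats.append({"type": "Feature", "geometry": mapping(cell.polygon),
                      "properties": props})
    _dump_json({"type": "FeatureCollection", "features": feats,
                "metadata": dict(surf.metadata, width_m=surf.grid.width_m)}, path)


def read_surface(path: str) -> AccessibilitySurface:
    with open(path, encoding="utf-8") as fh:
        data = json.load(fh)
    meta = data.get("metadata", {})
    cells, A, norm = [], [], []
    for feat in data["features"]:
        p = feat["properties"]
        poly = shape(feat["geometry"])
        cells.append(HexCell(cell_id=p["cell_id"], polygon=poly,
                             point=(poly.centroid.x, poly.centroid.y)))
        A.append(p["A"])
        norm.append(p.get("A_normalized"))
    grid = HexGrid(cells=cells, width_m=float(meta.get("width_m", 0.0) or 1.0))
    surf = AccessibilitySurface(grid=grid, A=np.asarray(A, dtype=float),
                                metadata={k: v for k, v in meta.items()
                                          if k != "width_m"})
    if all(v is not None for v in norm) and norm:
        surf.A_normalized = np.asarray(norm, dtype=float)
    return surf


def write_report(stats: dict, path: str) -> None:
    _dump_json(stats, path)


def read_report(path: str) -> dict:
    with open(path, encoding="utf-8") as fh:
        return json.load(fh)


def _dump_json(obj, path: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=1)
        fh.write("\n")


# ------------------------------------------------------------------- YAML

def load_yaml(path: str) -> dict:
    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise SchemaError(f"{path!r}: expected a YAML mapping")
    return data


def save_yaml(data: dict, path: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)
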