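"""Readers and writers for the toolkit's interchange formats.

Tabular records travel as UTF-8, comma-separated, header-required CSV with
dot decimals; polygons travel as RFC 7946 GeoJSON (lon-lat order, WGS84).
Readers validate field-level constraints (coordinate ranges, enum tokens)
and the referential integrity of the facility hierarchy; unknown facility
kinds or operators are rejected rather than coerced, because the
appropriateness metric depends on those enums.
"""

from __future__ import annotations

import json
from collections import defaultdict
from typing import Iterable, Sequence

import pandas as pd
from shapely.geometry import mapping, shape
from shapely.ops import unary_union

from .model import (
    CatchmentArea,
    Cluster,
    DistrictBoundary,
    FacilityKind,
    FacilityUnit,
    FormatError,
    IntegrityError,
    LastSource,
    LinkageResult,
    LinkMethod,
    Operator,
    Respondent,
    ServicePoint,
    ValidationError,
)

_POINT_COLUMNS = ["id", "kind", "operator", "parent_id", "lon", "lat", "district_id"]
_CLUSTER_COLUMNS = ["id", "true_lon", "true_lat", "obs_lon", "obs_lat", "urban", "district_id"]
_RESPONDENT_COLUMNS = ["id", "cluster_id", "modern_user", "last_source", "method"]
_LINKAGE_COLUMNS = ["cluster_id", "method", "radius_m", "facility_id"]


def _read_csv(path, required: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    return df


def _check_coord(lon: float, lat: float, row: int, path) -> None:
    if not (-180.0 <= lon <= 180.0 and -90.0 <= lat <= 90.0):
        raise ValidationError(f"{path}: coordinate out of range at data row {row}: lon={lon}, lat={lat}")


def _enum(cls, token: str, row: int, path, column: str):
    try:
        return cls(token)
    except ValueError:
        valid = [m.value for m in cls]
        raise ValidationError(
            f"{path}: unknown {column} token {token!r} at data row {row}; expected one of {valid}"
        ) from None


def read_service_points(path) -> list[ServicePoint]:
    """Read and validate a facility master list CSV.

    Every health post must resolve to an existing hospital/health center;
    hospitals and health centers must be self-parented.
    """
    df = _read_csv(path, _POINT_COLUMNS)
    points: list[ServicePoint] = []
    for row, rec in enumerate(df.itertuples(index=False)):
        lon, lat = float(rec.lon), float(rec.lat)
        _check_coord(lon, lat, row, path)
        points.append(
            ServicePoint(
                id=rec.id,
                kind=_enum(FacilityKind, rec.kind, row, path, "kind"),
                operator=_enum(Operator, rec.operator, row, path, "operator"),
                parent_id=rec.parent_id,
                lon=lon,
                lat=lat,
                district_id=rec.district_id,
            )
        )
    validate_hierarchy(points)
    return points


def validate_hierarchy(points: Sequence[ServicePoint]) -> None:
    ids = [p.id for p in points]
    if len(set(ids)) != len(ids):
        seen: set[str] = set()
        dupes = {i for i in ids if i in seen or seen.add(i)}
        raise IntegrityError(f"duplicate service point ids: {sorted(dupes)}")
    facility_ids = {p.id for p in points if p.is_facility}
    dangling = []
    for p in points:
        if p.is_facility:
            if p.parent_id != p.id:
                raise IntegrityError(f"{p.kind.value} {p.id!r} must be self-parented, got parent_id={p.parent_id!r}")
        elif p.parent_id not in facility_ids:
            dangling.append(p.id)
    if dangling:
        raise IntegrityError(f"health posts with dangling parent_id: {sorted(dangling)}")


def build_facility_units(points: Sequence[ServicePoint]) -> list[FacilityUnit]:
    """Group service points into facility units by parent_id.

    Returns one unit per hospital/health center; member sets partition the
    point ids.
    """
    validate_hierarchy(points)
    members: dict[str, set[str]] = defaultdict(set)
    kinds: dict[str, set[tuple[FacilityKind, Operator]]] = defaultdict(set)
    for p in points:
        members[p.parent_id].add(p.id)
        kinds[p.parent_id].add((p.kind, p.operator))
    return [
        FacilityUnit(facility_id=fid, members=frozenset(members[fid]), kinds_present=frozenset(kinds[fid]))
        for fid in sorted(members)
    ]


def write_service_points(points: Iterable[ServicePoint], path) -> None:
    pd.DataFrame(
        [
            {
                "id": p.id,
                "kind": p.kind.value,
                "operator": p.operator.value,
                "parent_id": p.parent_id,
                "lon": f"{p.lon:.10f}",
                "lat": f"{p.lat:.10f}",
                "district_id": p.district_id,
            }
            for p in points
        ],
        columns=_POINT_COLUMNS,
    ).to_csv(path, index=False)


def read_clusters(path) -> list[Cluster]:
    df = _read_csv(path, _CLUSTER_COLUMNS)
    clusters = []
    for row, rec in enumerate(df.itertuples(index=False)):
        obs_lon, obs_lat = float(rec.obs_lon), float(rec.obs_lat)
        _check_coord(obs_lon, obs_lat, row, path)
        # true coordinates are blank for real (non-simulated) inputs
        true_lon = float(rec.true_lon) if rec.true_lon != "" else obs_lon
        true_lat = float(rec.true_lat) if rec.true_lat != "" else obs_lat
        if rec.urban not in ("0", "1", "True", "False", "true", "false"):
            raise ValidationError(f"{path}: urban flag must be boolean at data row {row}, got {rec.urban!r}")
        clusters.append(
            Cluster(
                id=rec.id,
                true_lon=true_lon,
                true_lat=true_lat,
                obs_lon=obs_lon,
                obs_lat=obs_lat,
                urban=rec.urban in ("1", "True", "true"),
                district_id=rec.district_id,
            )
        )
    if len({c.id for c in clusters}) != len(clusters):
        raise IntegrityError(f"{path}: duplicate cluster ids")
    return clusters


def write_clusters(clusters: Iterable[Cluster], path) -> None:
    pd.DataFrame(
        [
            {
                "id": c.id,
                "true_lon": f"{c.true_lon:.10f}",
                "true_lat": f"{c.true_lat:.10f}",
                "obs_lon": f"{c.obs_lon:.10f}",
                "obs_lat": f"{c.obs_lat:.10f}",
                "urban": "1" if c.urban else "0",
                "district_id": c.district_id,
            }
            for c in clusters
        ],
        columns=_CLUSTER_COLUMNS,
    ).to_csv(path, index=False)


def read_respondents(path, clusters: Sequence[Cluster] | None = None) -> list[Respondent]:
    df = _read_csv(path, _RESPONDENT_COLUMNS[:4])  # method column optional
    has_method = "method" in df.columns
    out = []
    for row, rec in enumerate(df.itertuples(index=False)):
        modern = rec.modern_user in ("1", "True", "true")
        source = _enum(LastSource, rec.last_source, row, path, "last_source")
        if modern == (source == LastSource.NONE):
            raise ValidationError(
                f"{path}: last_source {source.value!r} inconsistent with modern_user={modern} at data row {row}"
            )
        out.append(
            Respondent(
                id=rec.id,
                cluster_id=rec.cluster_id,
                modern_user=modern,
                last_source=source,
                method=(rec.method or None) if has_method else None,
            )
        )
    if clusters is not None:
        known = {c.id for c in clusters}
        bad = sorted({r.cluster_id for r in out} - known)
        if bad:
            raise IntegrityError(f"{path}: respondents reference unknown clusters {bad}")
    return out


def write_respondents(respondents: Iterable[Respondent], path) -> None:
    pd.DataFrame(
        [
            {
                "id": r.id,
                "cluster_id": r.cluster_id,
                "modern_user": "1" if r.modern_user else "0",
                "last_source": r.last_source.value,
                "method": r.method or "",
            }
            for r in respondents
        ],
        columns=_RESPONDENT_COLUMNS,
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# GeoJSON


def _check_rings_closed(geom: dict, context: str) -> None:
    gtype = geom.get("type")
    if gtype == "Polygon":
        rings = geom["coordinates"]
    elif gtype == "MultiPolygon":
        rings = [r for poly in geom["coordinates"] for r in poly]
    else:
        raise FormatError(f"{context}: expected (Multi)Polygon geometry, got {gtype}")
    for ring in rings:
        if len(ring) < 4 or ring[0] != ring[-1]:
            raise FormatError(f"{context}: polygon ring not closed")


def _geom_from_feature(feature: dict, context: str):
    geom = feature.get("geometry")
    if geom is None:
        raise FormatError(f"{context}: feature without geometry")
    _check_rings_closed(geom, context)
    g = shape(geom)
    if not g.is_valid:
        raise FormatError(f"{context}: invalid (self-intersecting?) geometry")
    return g


def read_districts(path) -> list[DistrictBoundary]:
    """Read district boundary polygons from a GeoJSON FeatureCollection
    carrying a ``district_id`` property per feature."""
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("type") != "FeatureCollection":
        raise FormatError(f"{path}: expected a GeoJSON FeatureCollection")
    out = []
    for i, feature in enumerate(doc.get("features", [])):
        did = (feature.get("properties") or {}).get("district_id")
        if not did:
            raise FormatError(f"{path}: feature {i} lacks a district_id property")
        out.append(DistrictBoundary(district_id=did, geometry=_geom_from_feature(feature, f"{path} feature {i}")))
    if len({d.district_id for d in out}) != len(out):
        raise IntegrityError(f"{path}: duplicate district ids")
    return out


def write_districts(districts: Iterable[DistrictBoundary], path) -> None:
    doc = {
        "type": "FeatureCollection",
        "features": [
            {
                "type": "Feature",
                "properties": {"district_id": d.district_id},
                "geometry": mapping(d.geometry),
            }
            for d in districts
        ],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def read_region(path):
    """Read a study-region polygon: union of all geometries in the file."""
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("type") == "FeatureCollection":
        geoms = [_geom_from_feature(f, f"{path} feature {i}") for i, f in enumerate(doc["features"])]
    elif doc.get("type") == "Feature":
        geoms = [_geom_from_feature(doc, path)]
    else:
        _check_rings_closed(doc, str(path))
        geoms = [shape(doc)]
    return unary_union(geoms)


def write_region(geometry, path) -> None:
    with open(path, "w") as fh:
        json.dump({"type": "Feature", "properties": {}, "geometry": mapping(geometry)}, fh)


def write_catchments(catchments: Iterable[CatchmentArea], projector, path) -> None:
    """Export catchment polygons to GeoJSON, unprojected back to WGS84."""
    from shapely.ops import transform

    def to_lonlat(x, y):
        return projector.inverse(x, y)

    doc = {
        "type": "FeatureCollection",
        "features": [
            {
                "type": "Feature",
                "properties": {
                    "facility_id": c.facility_id,
                    "member_sites": sorted(c.member_sites),
                },
                "geometry": mapping(transform(to_lonlat, c.geometry)),
            }
            for c in catchments
        ],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


# ---------------------------------------------------------------------------
# Linkage tables and reports


def write_linkage_table(results: Iterable[LinkageResult], path) -> None:
    """One row per (cluster, method, facility); unlinked clusters keep a row
    with an empty facility_id so no cluster silently drops out."""
    rows = []
    for res in results:
        radius = "" if res.radius_m is None else f"{res.radius_m:.3f}"
        for cid in sorted(res.links):
            fids = sorted(res.links[cid])
            if not fids:
                rows.append({"cluster_id": cid, "method": res.method.value, "radius_m": radius, "facility_id": ""})
            for fid in fids:
                rows.append({"cluster_id": cid, "method": res.method.value, "radius_m": radius, "facility_id": fid})
    pd.DataFrame(rows, columns=_LINKAGE_COLUMNS).to_csv(path, index=False)


def read_linkage_table(path) -> list[LinkageResult]:
    df = _read_csv(path, _LINKAGE_COLUMNS)
    by_method: dict[tuple, dict[str, set[str]]] = defaultdict(dict)
    for row, rec in enumerate(df.itertuples(index=False)):
        method = _enum(LinkMethod, rec.method, row, path, "method")
        radius = float(rec.radius_m) if rec.radius_m != "" else None
        links = by_method[(method, radius)]
        links.setdefault(rec.cluster_id, set())
        if rec.facility_id:
            links[rec.cluster_id].add(rec.facility_id)
    return [
        LinkageResult(method=method, radius_m=radius, links={c: frozenset(s) for c, s in links.items()})
        for (method, radius), links in by_method.items()
    ]


def write_report(report_df: pd.DataFrame, path) -> None:
    report_df.to_csv(path, index=False)
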