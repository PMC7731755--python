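"""The four cluster-to-facility linking methods.

Clusters are linked to *facility units* (a hospital/health center with its
posts), never to individual posts:

- ``closest``   -- the single nearest facility point;
- ``buffer``    -- every facility point within a radius (default 5 km);
- ``admin``     -- every facility in the cluster's district (by attribute,
  not re-derived spatially, mirroring how surveys key clusters to the
  district they are displaced within);
- ``catchment`` -- every facility whose theoretical catchment polygon comes
  within the radius of the cluster; at radius 0 this is the containing
  catchment.

All methods use the observed (displaced) cluster coordinates and inclusive
(<=) distance boundaries.  The default candidate set is the public health
system -- government plus CHAM units; NGO/private units stay in the Voronoi
tessellation but are filtered out here.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np
from shapely import STRtree
from shapely.geometry import Point

from .model import (
    CatchmentArea,
    Cluster,
    FacilityUnit,
    IntegrityError,
    LinkageResult,
    LinkMethod,
    Operator,
    PUBLIC_OPERATORS,
    ServicePoint,
    ValidationError,
)

#: distances within this many meters of the minimum count as ties
TIE_TOL_M = 1e-9

CandidateFilter = Callable[[FacilityUnit, Operator], bool]


def candidate_filter(name: str) -> CandidateFilter:
    """Named candidate filters: ``public`` (government + CHAM) or ``all``."""
    if name == "public":
        return lambda unit, operator: operator in PUBLIC_OPERATORS
    if name == "all":
        return lambda unit, operator: True
    raise ValidationError(f"unknown candidate filter {name!r}; expected 'public' or 'all'")


def _facility_index(points: Sequence[ServicePoint]) -> dict[str, ServicePoint]:
    return {p.id: p for p in points if p.is_facility}


def _candidates(
    units: Sequence[FacilityUnit],
    facilities: dict[str, ServicePoint],
    selector: CandidateFilter | str,
) -> list[tuple[FacilityUnit, ServicePoint]]:
    if isinstance(selector, str):
        selector = candidate_filter(selector)
    out = []
    for u in sorted(units, key=lambda u: u.facility_id):
        fp = facilities.get(u.facility_id)
        if fp is None:
            raise IntegrityError(f"facility unit {u.facility_id!r} has no facility-level service point")
        if selector(u, fp.operator):
            out.append((u, fp))
    return out


def _projected(clusters: Sequence[Cluster], projector) -> np.ndarray:
    lon = np.array([c.obs_lon for c in clusters])
    lat = np.array([c.obs_lat for c in clusters])
    x, y = projector.forward(lon, lat)
    return np.column_stack([np.atleast_1d(x), np.atleast_1d(y)])


def link_closest(
    clusters: Sequence[Cluster],
    points: Sequence[ServicePoint],
    units: Sequence[FacilityUnit],
    projector,
    candidates: CandidateFilter | str = "public",
) -> LinkageResult:
    """Link each cluster to its single closest candidate facility point;
    ties go to the lexicographically smallest facility id."""
    cand = _candidates(units, _facility_index(points), candidates)
    if not cand:
        raise ValidationError("empty candidate set for closest-facility linkage")
    fx, fy = projector.forward(np.array([fp.lon for _, fp in cand]), np.array([fp.lat for _, fp in cand]))
    fids = np.array([u.facility_id for u, _ in cand])
    cxy = _projected(clusters, projector)
    links = {}
    for c, (x, y) in zip(clusters, cxy):
        d = np.hypot(fx - x, fy - y)
        tied = fids[d <= d.min() + TIE_TOL_M]
        links[c.id] = frozenset({min(tied)})
    return LinkageResult(method=LinkMethod.CLOSEST, links=links)


def link_buffer(
    clusters: Sequence[Cluster],
    points: Sequence[ServicePoint],
    units: Sequence[FacilityUnit],
    projector,
    radius_m: float = 5000.0,
    candidates: CandidateFilter | str = "public",
) -> LinkageResult:
    """Link each cluster to every candidate facility point within
    ``radius_m`` (inclusive); clusters may end up with an empty set."""
    if radius_m <= 0:
        raise ValidationError(f"buffer radius must be positive, got {radius_m}")
    cand = _candidates(units, _facility_index(points), candidates)
    fx, fy = projector.forward(np.array([fp.lon for _, fp in cand]), np.array([fp.lat for _, fp in cand]))
    fids = np.array([u.facility_id for u, _ in cand])
    cxy = _projected(clusters, projector)
    links = {}
    for c, (x, y) in zip(clusters, cxy):
        d = np.hypot(fx - x, fy - y)
        links[c.id] = frozenset(fids[d <= radius_m])
    return LinkageResult(method=LinkMethod.BUFFER, radius_m=radius_m, links=links)


def link_admin(
    clusters: Sequence[Cluster],
    points: Sequence[ServicePoint],
    units: Sequence[FacilityUnit],
    candidates: CandidateFilter | str = "public",
    known_districts: Sequence[str] | None = None,
) -> LinkageResult:
    """Link each cluster to all candidate facilities in its district, by
    the district_id attribute."""
    cand = _candidates(units, _facility_index(points), candidates)
    by_district: dict[str, set[str]] = {}
    for u, fp in cand:
        by_district.setdefault(fp.district_id, set()).add(u.facility_id)
    if known_districts is not None:
        known = set(known_districts)
        bad = sorted({c.district_id for c in clusters} - known) + sorted(set(by_district) - known)
        if bad:
            raise IntegrityError(f"unknown district ids: {bad}")
    links = {c.id: frozenset(by_district.get(c.district_id, set())) for c in clusters}
    return LinkageResult(method=LinkMethod.ADMIN, links=links)


def link_catchment(
    clusters: Sequence[Cluster],
    catchments: Sequence[CatchmentArea],
    projector,
    radius_m: float = 5000.0,
    candidates: CandidateFilter | str = "public",
    points: Sequence[ServicePoint] | None = None,
    units: Sequence[FacilityUnit] | None = None,
) -> LinkageResult:
    """Link each cluster to every candidate facility whose catchment polygon
    lies within ``radius_m`` of the cluster (inclusive); administrative
    boundaries are ignored.  At radius 0 a cluster strictly inside the
    region links exactly the catchment that contains it.

    Candidate filtering by operator needs ``points`` (and optionally
    ``units``); with the ``all`` filter they may be omitted.
    """
    if not catchments:
        raise ValidationError("no catchment areas supplied")
    if radius_m < 0:
        raise ValidationError(f"catchment radius must be >= 0, got {radius_m}")
    if isinstance(candidates, str):
        selector = candidate_filter(candidates)
    else:
        selector = candidates
    facilities = _facility_index(points) if points is not None else {}
    unit_by_id = {u.facility_id: u for u in units} if units is not None else {}

    kept = []
    for c in sorted(catchments, key=lambda c: c.facility_id):
        fp = facilities.get(c.facility_id)
        if fp is None and points is not None:
            raise IntegrityError(f"catchment {c.facility_id!r} has no facility-level service point")
        operator = fp.operator if fp is not None else None
        if fp is None or selector(unit_by_id.get(c.facility_id), operator):
            kept.append(c)
    tree = STRtree([c.geometry for c in kept])
    cxy = _projected(clusters, projector)
    pts = [Point(x, y) for x, y in cxy]
    links: dict[str, set[str]] = {c.id: set() for c in clusters}
    if radius_m > 0:
        pairs = tree.query(pts, predicate="dwithin", distance=radius_m)
    else:
        pairs = tree.query(pts, predicate="intersects")
    for ci, gi in zip(*pairs):
        links[clusters[ci].id].add(kept[gi].facility_id)
    return LinkageResult(
        method=LinkMethod.CATCHMENT,
        radius_m=radius_m,
        links={cid: frozenset(s) for cid, s in links.items()},
    )
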