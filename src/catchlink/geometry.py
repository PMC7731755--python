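"""Planar geometric primitives.

Geographic coordinates (WGS84 decimal degrees) are mapped into a locally
metric plane with a spherical azimuthal-equidistant projection centered on
the data extent.  Distances from the projection center are exact; over a
country-sized extent (a few hundred km) local distances are accurate to
well under 0.5%, which is far below the kilometers-scale buffers this
toolkit works with.  The projection is pluggable: any object with
``forward``/``inverse`` and a ``crs_tag`` can stand in (e.g. a UTM
transform for real national data).

The Voronoi partition is bounded: scipy's unbounded diagram is closed by
ring of distant ghost sites and every cell is clipped to the study region,
so the cells tile the region exactly.
"""

from __future__ import annotations

import math
from typing import NamedTuple, Sequence

import numpy as np
import shapely
from scipy.spatial import Voronoi, cKDTree
from shapely.geometry import Point, Polygon as ShapelyPolygon
from shapely.ops import unary_union

from .model import ValidationError

EARTH_RADIUS_M = 6_371_000.0

#: sites closer than this (meters) are considered coincident
SITE_DEDUP_TOL_M = 1.0


class ProjectedPoint(NamedTuple):
    x: float
    y: float
    crs_tag: str = ""


class UnsupportedRegionError(ValidationError):
    """Raised for near-polar inputs where the planar approximation breaks."""


class CrsMismatchError(ValidationError):
    """Two projected points carry different crs tags."""


class DuplicateSiteError(ValidationError):
    """Voronoi sites closer than the deduplication tolerance."""

    def __init__(self, pairs: Sequence[tuple[int, int]]):
        self.pairs = list(pairs)
        super().__init__(f"duplicate Voronoi sites (closer than {SITE_DEDUP_TOL_M} m): {self.pairs}")


class AzimuthalEquidistant:
    """Spherical azimuthal-equidistant projection about ``(center_lon,
    center_lat)``; x east, y north, meters."""

    def __init__(self, center_lon: float, center_lat: float, radius_m: float = EARTH_RADIUS_M):
        if abs(center_lat) >= 89.9:
            raise UnsupportedRegionError(f"projection center latitude {center_lat} too close to a pole")
        self.center_lon = float(center_lon)
        self.center_lat = float(center_lat)
        self.radius_m = float(radius_m)
        self._lam0 = math.radians(center_lon)
        self._phi0 = math.radians(center_lat)
        self.crs_tag = f"aeqd:{center_lon:.6f},{center_lat:.6f}"

    def forward(self, lon, lat):
        """Project lon/lat (degrees, scalar or array) to x/y meters."""
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        if np.any(np.abs(lat) >= 89.9):
            raise UnsupportedRegionError("latitude within 0.1 deg of a pole is unsupported")
        lam = np.radians(lon)
        phi = np.radians(lat)
        sin0, cos0 = math.sin(self._phi0), math.cos(self._phi0)
        dlam = lam - self._lam0
        cos_c = sin0 * np.sin(phi) + cos0 * np.cos(phi) * np.cos(dlam)
        cos_c = np.clip(cos_c, -1.0, 1.0)
        c = np.arccos(cos_c)
        # k = c / sin(c), -> 1 as c -> 0
        with np.errstate(invalid="ignore", divide="ignore"):
            k = np.where(c > 1e-12, c / np.sin(np.where(c > 1e-12, c, 1.0)), 1.0)
        x = self.radius_m * k * np.cos(phi) * np.sin(dlam)
        y = self.radius_m * k * (cos0 * np.sin(phi) - sin0 * np.cos(phi) * np.cos(dlam))
        if x.ndim == 0:
            return float(x), float(y)
        return x, y

    def inverse(self, x, y):
        """Inverse projection: x/y meters back to lon/lat degrees."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        rho = np.hypot(x, y)
        c = rho / self.radius_m
        sin0, cos0 = math.sin(self._phi0), math.cos(self._phi0)
        safe_rho = np.where(rho > 1e-12, rho, 1.0)
        sin_c, cos_c = np.sin(c), np.cos(c)
        phi = np.arcsin(np.clip(cos_c * sin0 + y * sin_c * cos0 / safe_rho, -1.0, 1.0))
        lam = self._lam0 + np.arctan2(x * sin_c, safe_rho * cos_c * cos0 - y * sin_c * sin0)
        lon = np.degrees(np.where(rho > 1e-12, lam, self._lam0))
        lat = np.degrees(np.where(rho > 1e-12, phi, self._phi0))
        if lon.ndim == 0:
            return float(lon), float(lat)
        return lon, lat

    def project_point(self, lon: float, lat: float) -> ProjectedPoint:
        x, y = self.forward(lon, lat)
        return ProjectedPoint(x, y, self.crs_tag)


def haversine_m(lon1, lat1, lon2, lat2, radius_m: float = EARTH_RADIUS_M) -> float:
    """Great-circle distance in meters on a sphere."""
    p1, p2 = math.radians(lat1), math.radians(lat2)
    dphi = p2 - p1
    dlam = math.radians(lon2 - lon1)
    a = math.sin(dphi / 2) ** 2 + math.cos(p1) * math.cos(p2) * math.sin(dlam / 2) ** 2
    return 2 * radius_m * math.asin(min(1.0, math.sqrt(a)))


def distance_m(a, b) -> float:
    """Euclidean distance between two projected points (meters).

    Accepts ``ProjectedPoint`` or any (x, y) pair; crs tags, when present on
    both, must agree.
    """
    tag_a = getattr(a, "crs_tag", "")
    tag_b = getattr(b, "crs_tag", "")
    if tag_a and tag_b and tag_a != tag_b:
        raise CrsMismatchError(f"crs mismatch: {tag_a!r} vs {tag_b!r}")
    return math.hypot(a[0] - b[0], a[1] - b[1])


def _order_ring(vertices: np.ndarray) -> np.ndarray:
    """Order the vertices of a convex cell counter-clockwise."""
    center = vertices.mean(axis=0)
    ang = np.arctan2(vertices[:, 1] - center[1], vertices[:, 0] - center[0])
    return vertices[np.argsort(ang)]


def voronoi_partition(sites: np.ndarray, region, dedup_tol_m: float = SITE_DEDUP_TOL_M) -> list:
    """Bounded Voronoi partition: one shapely polygon per site, clipped to
    ``region`` (a shapely polygon in the same projected plane).

    The cells tile the region.  Raises :class:`DuplicateSiteError` for site
    pairs closer than ``dedup_tol_m`` and :class:`ValidationError` for sites
    outside the region.
    """
    sites = np.asarray(sites, dtype=float)
    if sites.ndim != 2 or sites.shape[1] != 2 or len(sites) == 0:
        raise ValidationError("sites must be a non-empty (n, 2) array")
    if not np.all(np.isfinite(sites)):
        raise ValidationError("non-finite site coordinates")

    pts = shapely.points(sites[:, 0], sites[:, 1])
    inside = shapely.covers(region, pts)
    if not inside.all():
        bad = np.nonzero(~inside)[0].tolist()
        raise ValidationError(f"sites outside region at indices {bad}")

    if len(sites) > 1:
        pairs = cKDTree(sites).query_pairs(dedup_tol_m)
        if pairs:
            raise DuplicateSiteError(sorted(pairs))

    if len(sites) == 1:
        return [shapely.make_valid(region)]

    # ghost sites on a distant ring put every real site strictly inside the
    # convex hull, so every real cell is finite
    minx, miny, maxx, maxy = region.bounds
    cx, cy = (minx + maxx) / 2.0, (miny + maxy) / 2.0
    span = max(maxx - minx, maxy - miny, 1.0)
    r_ghost = 100.0 * span
    ang = np.linspace(0, 2 * np.pi, 8, endpoint=False)
    ghosts = np.column_stack([cx + r_ghost * np.cos(ang), cy + r_ghost * np.sin(ang)])
    vor = Voronoi(np.vstack([sites, ghosts]))

    cells = []
    for i in range(len(sites)):
        reg = vor.regions[vor.point_region[i]]
        assert -1 not in reg, "ghost ring failed to bound a cell"
        verts = _order_ring(vor.vertices[reg])
        cell = ShapelyPolygon(verts)
        if not cell.is_valid:
            cell = shapely.make_valid(cell)
        cells.append(cell.intersection(region))
    return cells


def dissolve(cells: Sequence, groups: Sequence) -> dict:
    """Merge Voronoi cells by group key -> one (multi)polygon per group.

    Union and total area are preserved; groups are pairwise
    interior-disjoint because the input cells are.
    """
    if len(cells) != len(groups):
        raise ValidationError("cells and groups must align")
    by_group: dict = {}
    for cell, g in zip(cells, groups):
        by_group.setdefault(g, []).append(cell)
    return {g: unary_union(members) for g, members in sorted(by_group.items())}


def point_polygon_distance(p, poly) -> float:
    """Distance in meters from a projected point to a polygon; 0 when the
    point lies inside or on the boundary."""
    return float(poly.distance(Point(p[0], p[1])))
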