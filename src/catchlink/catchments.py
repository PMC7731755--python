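"""Theoretical catchment areas.

A facility unit's catchment is built by tessellating the study region into
Thiessen (Voronoi) polygons around *every* service point -- hospitals,
health centers, and all lower-level posts -- and then dissolving the cells
by owning facility.  Using the posts as Voronoi sites is what makes a
catchment reflect a facility's outreach geography rather than just its own
location.  Catchments partition the region and never overlap; a unit whose
posts are geographically separated may own a multi-part catchment, which is
kept as-is.

NGO/private facilities participate in the tessellation (removing their
sites would distort neighbouring catchments); whether they are *linkable*
is decided later by the linkage candidate filter.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree

from . import geometry
from .model import CatchmentArea, FacilityUnit, ServicePoint, ValidationError


def _merge_coincident_sites(
    coords: np.ndarray, ids: list[str], owner: dict[str, str], tol_m: float
) -> tuple[np.ndarray, list[list[str]]]:
    """Pool service points closer than ``tol_m`` into single Voronoi sites.

    Coincident GPS fixes would otherwise break the tessellation.  Each
    merged site keeps the full list of pooled point ids; its cell is later
    assigned to the unit owning the lexicographically smallest pooled id.
    """
    tree = cKDTree(coords)
    pairs = tree.query_pairs(tol_m)
    parent = list(range(len(ids)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i, j in pairs:
        parent[find(i)] = find(j)
    groups: dict[int, list[int]] = {}
    for i in range(len(ids)):
        groups.setdefault(find(i), []).append(i)
    site_coords, site_members = [], []
    for members in groups.values():
        members = sorted(members, key=lambda i: ids[i])
        site_coords.append(coords[members].mean(axis=0))
        site_members.append([ids[i] for i in members])
    return np.array(site_coords), site_members


def build_catchments(
    points: Sequence[ServicePoint],
    units: Sequence[FacilityUnit],
    region,
    projector,
) -> list[CatchmentArea]:
    """Build one catchment area per facility unit.

    ``region`` is a shapely polygon in the projected plane of ``projector``.
    Every member site ends up at distance 0 from its unit's catchment, the
    catchments are pairwise interior-disjoint, and their areas sum to the
    region's area.
    """
    if not points:
        raise ValidationError("no service points")
    owner: dict[str, str] = {}
    for u in units:
        for m in u.members:
            owner[m] = u.facility_id
    missing = sorted({p.id for p in points} - set(owner))
    if missing:
        raise ValidationError(f"service points not covered by any facility unit: {missing}")

    ids = [p.id for p in points]
    lon = np.array([p.lon for p in points])
    lat = np.array([p.lat for p in points])
    x, y = projector.forward(lon, lat)
    coords = np.column_stack([np.atleast_1d(x), np.atleast_1d(y)])

    site_coords, site_members = _merge_coincident_sites(coords, ids, owner, geometry.SITE_DEDUP_TOL_M)
    cells = geometry.voronoi_partition(site_coords, region)
    site_owner = [owner[members[0]] for members in site_members]
    dissolved = geometry.dissolve(cells, site_owner)

    members_by_owner: dict[str, set[str]] = {u.facility_id: set() for u in units}
    for members, fid in zip(site_members, site_owner):
        members_by_owner[fid].update(members)

    out = []
    for u in units:
        geom = dissolved.get(u.facility_id)
        if geom is None:
            # unit whose sole site was pooled into a neighbour's site
            continue
        out.append(
            CatchmentArea(
                facility_id=u.facility_id,
                geometry=geom,
                member_sites=frozenset(members_by_owner[u.facility_id]),
            )
        )
    return out
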