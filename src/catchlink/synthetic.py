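"""Synthetic landscape generator.

Generates a complete, self-consistent study landscape -- district polygons,
a three-level facility hierarchy, rural survey clusters, and individual
respondents -- with the statistical structure the linkage analysis assumes,
so every stage of the toolkit can be exercised end-to-end without any
restricted survey or master-list data.

The country is an elongated rectangle (~250 x 850 km, a Malawi-like aspect
ratio) split into Voronoi districts.  Population concentrates in a few
urban foci plus many small rural settlements; facilities and clusters are
drawn from that shared density surface, which is what produces the
realistic regime where roughly two-thirds of rural clusters sit within
5 km of a hospital or health center.  Lower-level posts scatter around
their parent facility with an exponentially decaying distance profile.

Each respondent's true source of modern contraception is known exactly
(the generator's ground truth): with probability ``p_home`` it is the
facility unit owning the catchment the cluster *truly* lies in, otherwise
a random other public unit -- emulating bypassing.  Respondents whose true
catchment is owned by an NGO/private unit report an unlinkable source, as
do a ``p_unlinkable`` share of all users (community agents, NGO outlets,
private clinics...).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree
from shapely.geometry import box

from . import geometry
from .geodata_io import build_facility_units
from .model import (
    Cluster,
    DistrictBoundary,
    FacilityKind,
    FacilityUnit,
    LastSource,
    Operator,
    PUBLIC_OPERATORS,
    Respondent,
    ServicePoint,
    ValidationError,
)

#: last-source mix among linkable respondents (master-list denominator
#: shares: health centers dominate, then hospitals, CHAM, posts)
SOURCE_KIND_WEIGHTS = {
    FacilityKind.HOSPITAL: 2287.0,
    FacilityKind.HEALTH_CENTER: 4948.0,
    FacilityKind.HEALTH_POST: 552.0,
}

#: contraceptive-method mixes (counts) for women eligible vs ineligible for
#: linkage; defaults reproduce the published rural contraceptive mix
INCLUDED_METHOD_COUNTS = {
    "injection": 4392, "female_sterilization": 1388, "implants": 1857,
    "male_condom": 353, "pill": 286, "iud": 138, "lactation": 0,
    "male_sterilization": 12, "standard_days": 8, "female_condom": 4,
    "emergency": 0, "other_modern": 2,
}
INELIGIBLE_METHOD_COUNTS = {
    "injection": 805, "female_sterilization": 429, "implants": 355,
    "male_condom": 289, "pill": 101, "iud": 36, "lactation": 16,
    "male_sterilization": 8, "standard_days": 7, "female_condom": 3,
    "emergency": 2, "other_modern": 1,
}


@dataclass(frozen=True)
class LandscapeParams:
    """Parameters of the synthetic landscape; the defaults emulate the
    published national study scale."""

    n_districts: int = 28
    n_hospitals: int = 85
    n_health_centers: int = 542
    n_posts: int = 8870
    n_gov_facilities: int = 450
    n_cham_facilities: int = 145
    n_clusters: int = 817
    women_per_cluster_mean: float = 12.9
    women_per_cluster_shape: float = 4.0
    modern_use_rate: float = 0.4475
    p_unlinkable: float = 0.1956
    #: probability a linkable respondent's true source is her home unit
    p_home: float = 0.85
    country_width_km: float = 250.0
    country_height_km: float = 850.0
    center_lon: float = 34.3
    center_lat: float = -13.3
    n_urban_foci: int = 4
    urban_sigma_km: float = 10.0
    n_settlements: int = 60
    settlement_sigma_km: float = 4.5
    #: weight of the settlement component in the shared density surface
    p_settlement: float = 0.85
    #: share of hospitals/health centers placed near urban foci
    facility_urban_frac: float = 0.2
    #: how strongly NGO/private operators concentrate at urban facilities
    ngo_urban_bias: float = 9.0
    post_distance_scale_km: float = 3.0
    post_max_distance_km: float = 15.0
    seed: int = 0

    def __post_init__(self):
        if min(self.n_districts, self.n_hospitals, self.n_health_centers, self.n_clusters) < 1:
            raise ValidationError("landscape counts must be positive")
        n_fac = self.n_hospitals + self.n_health_centers
        if self.n_gov_facilities + self.n_cham_facilities > n_fac:
            raise ValidationError(
                f"operator mix ({self.n_gov_facilities} gov + {self.n_cham_facilities} CHAM) "
                f"exceeds {n_fac} hospitals + health centers"
            )
        for p in (self.modern_use_rate, self.p_unlinkable, self.p_home, self.p_settlement):
            if not 0.0 <= p <= 1.0:
                raise ValidationError("probabilities must be in [0, 1]")

    def scaled(self, factor: float) -> "LandscapeParams":
        """Scale the landscape counts for desk-sized runs, preserving the
        density regime (area shrinks with the counts)."""
        if factor <= 0:
            raise ValidationError("size factor must be positive")

        def n(v, lo=1):
            return max(lo, int(round(v * factor)))

        return replace(
            self,
            n_districts=n(self.n_districts),
            n_hospitals=n(self.n_hospitals),
            n_health_centers=n(self.n_health_centers, lo=2),
            n_posts=n(self.n_posts),
            n_gov_facilities=n(self.n_gov_facilities, lo=2),
            n_cham_facilities=n(self.n_cham_facilities, lo=0),
            n_clusters=n(self.n_clusters, lo=2),
            n_urban_foci=n(self.n_urban_foci),
            n_settlements=n(self.n_settlements),
            country_height_km=max(80.0, self.country_height_km * factor),
        )


@dataclass
class Landscape:
    params: LandscapeParams
    projector: geometry.AzimuthalEquidistant
    region: object  # shapely polygon, projected meters
    districts: list[DistrictBoundary]
    district_geoms: dict[str, object]  # projected polygons by district_id
    service_points: list[ServicePoint]
    units: list[FacilityUnit]
    clusters: list[Cluster]
    respondents: list[Respondent]
    truth: dict[str, str] = field(default_factory=dict)
    far_regime: dict[str, bool] = field(default_factory=dict)

    def ground_truth(self, respondents: Optional[Sequence[Respondent]] = None) -> dict[str, str]:
        """True source facility unit per linkable respondent."""
        if respondents is None:
            return dict(self.truth)
        return {r.id: self.truth[r.id] for r in respondents if r.id in self.truth}


def _sample_mixture(n, rng, components, bounds):
    """Draw n points from a mixture of isotropic Gaussians + a uniform
    background, rejected into the bounding rectangle.

    ``components`` is a list of (prob, foci array, sigma); residual
    probability mass is uniform over the rectangle.
    """
    minx, miny, maxx, maxy = bounds
    out = np.empty((n, 2))
    probs = np.array([p for p, _, _ in components])
    which = rng.choice(len(components) + 1, size=n, p=np.append(probs, 1.0 - probs.sum()))
    for i in range(n):
        k = which[i]
        if k == len(components):
            out[i] = rng.uniform([minx, miny], [maxx, maxy])
            continue
        _, foci, sigma = components[k]
        f = foci[rng.integers(len(foci))]
        while True:
            p = f + rng.normal(0.0, sigma, size=2)
            if minx <= p[0] <= maxx and miny <= p[1] <= maxy:
                out[i] = p
                break
    return out


def generate_landscape(params: LandscapeParams) -> Landscape:
    """Generate a full landscape; deterministic given ``params.seed``."""
    rng = np.random.default_rng(params.seed)
    W = params.country_width_km * 1000.0
    H = params.country_height_km * 1000.0
    region = box(-W / 2, -H / 2, W / 2, H / 2)
    bounds = region.bounds
    projector = geometry.AzimuthalEquidistant(params.center_lon, params.center_lat)

    # --- districts: Voronoi cells of uniform seeds -----------------------
    district_seeds = rng.uniform([bounds[0], bounds[1]], [bounds[2], bounds[3]], size=(params.n_districts, 2))
    district_cells = geometry.voronoi_partition(district_seeds, region)
    width = len(str(params.n_districts))
    district_ids = [f"D{i + 1:0{width}d}" for i in range(params.n_districts)]
    district_tree = cKDTree(district_seeds)

    def district_of(xy: np.ndarray) -> list[str]:
        _, idx = district_tree.query(xy)
        return [district_ids[i] for i in np.atleast_1d(idx)]

    # --- density surface -------------------------------------------------
    margin = 0.12
    lo = np.array([bounds[0], bounds[1]])
    hi = np.array([bounds[2], bounds[3]])
    span = hi - lo
    urban_foci = rng.uniform(lo + margin * span, hi - margin * span, size=(params.n_urban_foci, 2))
    settlements = rng.uniform(lo + 0.03 * span, hi - 0.03 * span, size=(params.n_settlements, 2))
    sig_u = params.urban_sigma_km * 1000.0
    sig_s = params.settlement_sigma_km * 1000.0

    # --- hospitals and health centers ------------------------------------
    n_fac = params.n_hospitals + params.n_health_centers
    fu = params.facility_urban_frac
    fac_components = [
        (fu, urban_foci, sig_u),
        ((1.0 - fu) * params.p_settlement, settlements, sig_s),
    ]
    fac_xy = _sample_mixture(n_fac, rng, fac_components, bounds)
    # label the component actually used to bias hospital/NGO assignment
    d_urb = cKDTree(urban_foci).query(fac_xy)[0]
    urbanish = d_urb < 3.0 * sig_u

    w_hosp = np.where(urbanish, 4.0, 1.0)
    hosp_idx = rng.choice(n_fac, size=params.n_hospitals, replace=False, p=w_hosp / w_hosp.sum())
    is_hospital = np.zeros(n_fac, dtype=bool)
    is_hospital[hosp_idx] = True

    n_ngo = n_fac - params.n_gov_facilities - params.n_cham_facilities
    operators = [Operator.GOVERNMENT] * n_fac
    w_ngo = np.where(urbanish, params.ngo_urban_bias, 1.0)
    ngo_idx = rng.choice(n_fac, size=n_ngo, replace=False, p=w_ngo / w_ngo.sum())
    for i in ngo_idx:
        operators[i] = Operator.NGO
    remaining = np.setdiff1d(np.arange(n_fac), ngo_idx)
    cham_idx = rng.choice(remaining, size=params.n_cham_facilities, replace=False)
    for i in cham_idx:
        operators[i] = Operator.CHAM

    hosp_w = len(str(params.n_hospitals))
    hc_w = len(str(params.n_health_centers))
    fac_ids, n_h, n_c = [], 0, 0
    for i in range(n_fac):
        if is_hospital[i]:
            n_h += 1
            fac_ids.append(f"H{n_h:0{hosp_w}d}")
        else:
            n_c += 1
            fac_ids.append(f"C{n_c:0{hc_w}d}")

    fac_districts = district_of(fac_xy)
    lon, lat = projector.inverse(fac_xy[:, 0], fac_xy[:, 1])
    points: list[ServicePoint] = [
        ServicePoint(
            id=fac_ids[i],
            kind=FacilityKind.HOSPITAL if is_hospital[i] else FacilityKind.HEALTH_CENTER,
            operator=operators[i],
            parent_id=fac_ids[i],
            lon=lon[i],
            lat=lat[i],
            district_id=fac_districts[i],
        )
        for i in range(n_fac)
    ]

    # --- lower-level posts around their parents ---------------------------
    post_counts = rng.multinomial(params.n_posts, rng.dirichlet(np.full(n_fac, 2.0)))
    scale = params.post_distance_scale_km * 1000.0
    d_cap = params.post_max_distance_km * 1000.0
    post_w = len(str(max(params.n_posts, 1)))
    post_xy_all, post_parent = [], []
    k = 0
    for i in range(n_fac):
        for _ in range(post_counts[i]):
            k += 1
            for _attempt in range(1000):
                dist = rng.exponential(scale)
                if dist > d_cap:
                    continue
                theta = rng.uniform(0, 2 * np.pi)
                p = fac_xy[i] + dist * np.array([np.cos(theta), np.sin(theta)])
                if bounds[0] <= p[0] <= bounds[2] and bounds[1] <= p[1] <= bounds[3]:
                    break
            else:
                p = fac_xy[i] + rng.normal(0, 10.0, size=2)  # sliver fallback: hug the parent
            post_xy_all.append(p)
            post_parent.append(i)
    post_xy = np.array(post_xy_all).reshape(-1, 2)
    if len(post_xy):
        plon, plat = projector.inverse(post_xy[:, 0], post_xy[:, 1])
        post_districts = district_of(post_xy)
        for j in range(len(post_xy)):
            i = post_parent[j]
            points.append(
                ServicePoint(
                    id=f"P{j + 1:0{post_w}d}",
                    kind=FacilityKind.HEALTH_POST,
                    operator=operators[i],
                    parent_id=fac_ids[i],
                    lon=plon[j],
                    lat=plat[j],
                    district_id=post_districts[j],
                )
            )

    units = build_facility_units(points)
    unit_by_id = {u.facility_id: u for u in units}

    # --- clusters (rural) -------------------------------------------------
    cl_xy = _sample_mixture(
        params.n_clusters, rng, [(params.p_settlement, settlements, sig_s)], bounds
    )
    cl_districts = district_of(cl_xy)
    cl_w = len(str(params.n_clusters))
    clon, clat = projector.inverse(cl_xy[:, 0], cl_xy[:, 1])
    clusters = [
        Cluster(
            id=f"CL{i + 1:0{cl_w}d}",
            true_lon=clon[i],
            true_lat=clat[i],
            obs_lon=clon[i],
            obs_lat=clat[i],
            urban=False,
            district_id=cl_districts[i],
        )
        for i in range(params.n_clusters)
    ]

    # --- true catchment owner per cluster: unit of the nearest site ------
    all_xy = np.array([projector.forward(p.lon, p.lat) for p in points])
    site_tree = cKDTree(all_xy)
    owner_of_cluster = {}
    _, nearest = site_tree.query(cl_xy)
    parent_of = {p.id: p.parent_id for p in points}
    ordered_ids = [p.id for p in points]
    for c, site_i in zip(clusters, np.atleast_1d(nearest)):
        owner_of_cluster[c.id] = parent_of[ordered_ids[site_i]]

    # --- respondents ------------------------------------------------------
    public_units = sorted(u.facility_id for u in units if _unit_operator(u) in PUBLIC_OPERATORS)
    if not public_units:
        raise ValidationError("landscape has no public (government/CHAM) facility units")
    inc_methods, inc_p = _mix_probs(INCLUDED_METHOD_COUNTS)
    inel_methods, inel_p = _mix_probs(INELIGIBLE_METHOD_COUNTS)

    shape = params.women_per_cluster_shape
    theta = params.women_per_cluster_mean / shape
    respondents: list[Respondent] = []
    truth: dict[str, str] = {}
    rid = 0
    for c in clusters:
        n_women = max(1, int(round(rng.gamma(shape, theta))))
        for _ in range(n_women):
            rid += 1
            r_id = f"R{rid:06d}"
            if rng.random() >= params.modern_use_rate:
                respondents.append(Respondent(r_id, c.id, False, LastSource.NONE))
                continue
            if rng.random() < params.p_unlinkable:
                respondents.append(
                    Respondent(r_id, c.id, True, LastSource.OTHER_UNLINKABLE,
                               method=str(rng.choice(inel_methods, p=inel_p)))
                )
                continue
            owner = owner_of_cluster[c.id]
            owner_unit = unit_by_id[owner]
            if _unit_operator(owner_unit) not in PUBLIC_OPERATORS:
                # home catchment is NGO/private-owned: the source exists but
                # is not on the linkable master-list categories
                respondents.append(
                    Respondent(r_id, c.id, True, LastSource.OTHER_UNLINKABLE,
                               method=str(rng.choice(inel_methods, p=inel_p)))
                )
                continue
            if rng.random() < params.p_home or len(public_units) == 1:
                unit = owner_unit
            else:
                while True:
                    pick = public_units[rng.integers(len(public_units))]
                    if pick != owner:
                        unit = unit_by_id[pick]
                        break
            source = _draw_source(unit, rng)
            truth[r_id] = unit.facility_id
            respondents.append(
                Respondent(r_id, c.id, True, source, method=str(rng.choice(inc_methods, p=inc_p)))
            )

    lon_lat_districts = []
    from shapely.ops import transform

    for did, cell in zip(district_ids, district_cells):
        geom = transform(lambda x, y: projector.inverse(x, y), _densify(cell))
        lon_lat_districts.append(DistrictBoundary(district_id=did, geometry=geom))

    return Landscape(
        params=params,
        projector=projector,
        region=region,
        districts=lon_lat_districts,
        district_geoms=dict(zip(district_ids, district_cells)),
        service_points=points,
        units=units,
        clusters=clusters,
        respondents=respondents,
        truth=truth,
    )


def _densify(geom, max_segment_m: float = 10_000.0):
    """Insert vertices so straight projected edges stay straight-ish after
    unprojection."""
    import shapely

    return shapely.segmentize(geom, max_segment_m)


def _unit_operator(unit: FacilityUnit) -> Operator:
    """Operator of the unit's facility-level point (units are generated
    with one operator across members)."""
    ops = {op for _, op in unit.kinds_present}
    return next(iter(ops)) if len(ops) == 1 else Operator.GOVERNMENT


def _mix_probs(counts: dict[str, int]):
    labels = [k for k, v in counts.items() if v > 0]
    vals = np.array([counts[k] for k in labels], dtype=float)
    return labels, vals / vals.sum()


def _draw_source(unit: FacilityUnit, rng) -> LastSource:
    """Collapsed last-source category for a respondent served by ``unit``."""
    if _unit_operator(unit) == Operator.CHAM:
        return LastSource.CHAM
    kinds = sorted({k for k, op in unit.kinds_present if op == Operator.GOVERNMENT}, key=lambda k: k.value)
    w = np.array([SOURCE_KIND_WEIGHTS[k] for k in kinds])
    kind = kinds[rng.choice(len(kinds), p=w / w.sum())]
    return {
        FacilityKind.HOSPITAL: LastSource.GOV_HOSPITAL,
        FacilityKind.HEALTH_CENTER: LastSource.GOV_HEALTH_CENTER,
        FacilityKind.HEALTH_POST: LastSource.GOV_HEALTH_POST,
    }[kind]
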