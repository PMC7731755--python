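"""Domain model for cluster-to-facility geospatial linkage.

The unit of linkage throughout the toolkit is the *facility unit*: a
hospital or health center together with all of its affiliated lower-level
service points (health posts, village clinics, outreach posts).  Survey
clusters carry both a true location (known only in simulation) and an
observed, privacy-displaced location; all linkage operates on the observed
location, while the true location feeds simulation oracles.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional


class CatchlinkError(Exception):
    """Base class for all toolkit errors."""


class FormatError(CatchlinkError):
    """A file does not conform to the expected format (missing column,
    malformed geometry, unclosed ring...)."""


class ValidationError(CatchlinkError):
    """A record violates a field-level constraint (coordinate range,
    unknown enum token...)."""


class IntegrityError(CatchlinkError):
    """Referential integrity violated (dangling parent_id, respondent in an
    unknown cluster...)."""


class FacilityKind(str, enum.Enum):
    HOSPITAL = "hospital"
    HEALTH_CENTER = "health_center"
    HEALTH_POST = "health_post"


class Operator(str, enum.Enum):
    GOVERNMENT = "government"
    CHAM = "CHAM"
    NGO = "NGO"
    PRIVATE = "private"


#: Operators that make up the public health system for linkage purposes;
#: CHAM facilities are publicly funded and included.
PUBLIC_OPERATORS = frozenset({Operator.GOVERNMENT, Operator.CHAM})


class LastSource(str, enum.Enum):
    """Collapsed last-source-of-modern-contraception categories.

    Five categories are linkable against the facility master list
    (government hospitals / health centers / health posts, and CHAM
    facilities of any level collapsed into one category).  Everything else
    (NGO outlets, private clinics, community distribution agents, shops,
    friends...) is ``other_unlinkable``; non-users carry ``none``.
    """

    GOV_HOSPITAL = "gov_hospital"
    GOV_HEALTH_CENTER = "gov_health_center"
    GOV_HEALTH_POST = "gov_health_post"
    CHAM = "cham"
    OTHER_UNLINKABLE = "other_unlinkable"
    NONE = "none"


#: The four last-source categories that enter the appropriateness metric.
LINKABLE_SOURCES = (
    LastSource.GOV_HOSPITAL,
    LastSource.GOV_HEALTH_CENTER,
    LastSource.GOV_HEALTH_POST,
    LastSource.CHAM,
)


@dataclass(frozen=True)
class ServicePoint:
    """Any mapped service location: hospital, health center or lower-level
    post/village clinic.  Hospitals and health centers are self-parented;
    posts point at the hospital/health center that owns them."""

    id: str
    kind: FacilityKind
    operator: Operator
    parent_id: str
    lon: float
    lat: float
    district_id: str

    @property
    def is_facility(self) -> bool:
        """True for hospitals and health centers (the linkable levels)."""
        return self.kind in (FacilityKind.HOSPITAL, FacilityKind.HEALTH_CENTER)


@dataclass(frozen=True)
class FacilityUnit:
    """A hospital/health center plus its affiliated service points -- the
    unit of linkage.  ``kinds_present`` drives appropriateness matching."""

    facility_id: str
    members: frozenset[str]
    kinds_present: frozenset[tuple[FacilityKind, Operator]]

    def offers(self, kind: FacilityKind, operator: Operator) -> bool:
        return (kind, operator) in self.kinds_present

    def offers_operator(self, operator: Operator) -> bool:
        return any(op == operator for _, op in self.kinds_present)


@dataclass
class Cluster:
    """A survey sampling point.  ``obs_*`` is the displaced location used
    for analysis; ``true_*`` is known only in simulation."""

    id: str
    true_lon: float
    true_lat: float
    obs_lon: float
    obs_lat: float
    urban: bool
    district_id: str


@dataclass(frozen=True)
class Respondent:
    id: str
    cluster_id: str
    modern_user: bool
    last_source: LastSource
    #: contraceptive method label (synthetic landscapes assign these from a
    #: configurable mix); optional on real inputs
    method: Optional[str] = None


@dataclass(frozen=True)
class DistrictBoundary:
    """An administrative district polygon (possibly multi-part, e.g. an
    island district).  Geometry is stored in lon/lat decimal degrees."""

    district_id: str
    geometry: object  # shapely (Multi)Polygon in WGS84 lon/lat


@dataclass(frozen=True)
class CatchmentArea:
    """The merged Thiessen polygon owned by one facility unit, in projected
    meters.  May be multi-part when a unit's posts are geographically
    separated."""

    facility_id: str
    geometry: object  # shapely (Multi)Polygon, projected meters
    member_sites: frozenset[str]


class LinkMethod(str, enum.Enum):
    CLOSEST = "closest"
    BUFFER = "buffer"
    ADMIN = "admin"
    CATCHMENT = "catchment"


@dataclass
class LinkageResult:
    """Per-cluster link sets for one method.  Empty sets are retained so
    that unlinked clusters stay visible to the evaluation."""

    method: LinkMethod
    links: dict[str, frozenset[str]]
    radius_m: Optional[float] = None

    def n_clusters(self) -> int:
        return len(self.links)

    def linked_ids(self) -> list[str]:
        return [cid for cid, fids in self.links.items() if fids]
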