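"""DHS-style cluster displacement.

Survey programs displace cluster coordinates before release to protect
respondent privacy: rural clusters move up to 5 km in a random direction,
a randomly selected 1% of rural clusters up to 10 km, and urban clusters
up to 2 km -- always staying inside the district the cluster truly belongs
to.  This module simulates that procedure so the linkage methods can be
stress-tested against known true locations.

The displaced distance is drawn Uniform(0, d_max) (the published DHS
procedure says only "up to"); containment is enforced by rejection
sampling that re-draws both angle and distance, preserving the stated
marginal distribution conditional on staying inside the district.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from shapely.geometry import Point

from .model import Cluster, IntegrityError, ValidationError


@dataclass(frozen=True)
class DisplacementParams:
    rural_max_m: float = 5000.0
    #: share of rural clusters displaced under the long-range regime
    rural_far_fraction: float = 0.01
    rural_far_max_m: float = 10000.0
    urban_max_m: float = 2000.0
    max_attempts: int = 10000

    def __post_init__(self):
        if min(self.rural_max_m, self.rural_far_max_m, self.urban_max_m) < 0:
            raise ValidationError("displacement maxima must be >= 0")
        if not 0.0 <= self.rural_far_fraction <= 1.0:
            raise ValidationError("rural_far_fraction must be in [0, 1]")


def displace(
    clusters: Sequence[Cluster],
    district_geoms: dict[str, object],
    params: DisplacementParams,
    projector,
    seed: int,
) -> tuple[list[Cluster], list[bool]]:
    """Displace each cluster's true location into its observed location.

    ``district_geoms`` maps district_id to a shapely polygon in the
    projected plane of ``projector``.  Returns the displaced clusters and a
    per-cluster flag marking which rural clusters drew the long-range
    (10 km) regime.  Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    out: list[Cluster] = []
    far_flags: list[bool] = []
    for c in clusters:
        poly = district_geoms.get(c.district_id)
        if poly is None:
            raise IntegrityError(f"cluster {c.id!r}: unknown district {c.district_id!r}")
        if c.urban:
            d_max, far = params.urban_max_m, False
        else:
            far = bool(rng.random() < params.rural_far_fraction)
            d_max = params.rural_far_max_m if far else params.rural_max_m
        x0, y0 = projector.forward(c.true_lon, c.true_lat)
        if not poly.covers(Point(x0, y0)):
            raise IntegrityError(f"cluster {c.id!r}: true location outside district {c.district_id!r}")
        if d_max == 0:
            out.append(replace(c, obs_lon=c.true_lon, obs_lat=c.true_lat))
            far_flags.append(far)
            continue
        for _ in range(params.max_attempts):
            theta = rng.uniform(0.0, 2.0 * np.pi)
            dist = rng.uniform(0.0, d_max)
            x, y = x0 + dist * np.cos(theta), y0 + dist * np.sin(theta)
            if poly.covers(Point(x, y)):
                lon, lat = projector.inverse(x, y)
                out.append(replace(c, obs_lon=lon, obs_lat=lat))
                far_flags.append(far)
                break
        else:
            raise ValidationError(
                f"cluster {c.id!r}: no in-district displacement found in {params.max_attempts} attempts"
            )
    return out, far_flags
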