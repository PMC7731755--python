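import numpy as np
import pytest
from shapely.geometry import box

from catchlink import displacement, geometry, synthetic
from catchlink.model import FacilityKind, Operator, ServicePoint


@pytest.fixture(scope="session")
def projector():
    return geometry.AzimuthalEquidistant(34.3, -13.3)


@pytest.fixture(scope="session")
def square_region():
    """100 x 100 km square in projected meters."""
    return box(0.0, 0.0, 100_000.0, 100_000.0)


@pytest.fixture(scope="session")
def small_landscape():
    """A desk-sized landscape (~60 units, ~80 clusters), undisplaced."""
    return synthetic.generate_landscape(synthetic.LandscapeParams(seed=7).scaled(0.1))


@pytest.fixture(scope="session")
def full_landscape():
    """The default (study-scale) landscape with displaced clusters."""
    land = synthetic.generate_landscape(synthetic.LandscapeParams(seed=11))
    land.clusters, _ = displacement.displace(
        land.clusters, land.district_geoms, displacement.DisplacementParams(), land.projector, seed=12
    )
    return land


def make_point(pid, kind, lon, lat, parent=None, operator=Operator.GOVERNMENT, district="D1"):
    return ServicePoint(
        id=pid, kind=kind, operator=operator,
        parent_id=parent if parent is not None else pid,
        lon=lon, lat=lat, district_id=district,
    )


@pytest.fixture
def tiny_hierarchy():
    """One hospital self-parented with two posts pointing at it."""
    return [
        make_point("H1", FacilityKind.HOSPITAL, 34.0, -13.0),
        make_point("P1", FacilityKind.HEALTH_POST, 34.05, -13.02, parent="H1"),
        make_point("P2", FacilityKind.HEALTH_POST, 33.95, -12.98, parent="H1"),
    ]


def nearest_site_bruteforce(samples: np.ndarray, sites: np.ndarray) -> np.ndarray:
    """Index of the nearest site for each sample point (exhaustive)."""
    d2 = ((samples[:, None, :] - sites[None, :, :]) ** 2).sum(axis=2)
    return d2.argmin(axis=1)
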