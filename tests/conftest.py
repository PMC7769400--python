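import math

import numpy as np
import pytest

from fidreg import EulerAngles6D, build_phantom, cloud_from_points, euler_to_transform


def random_transform(rng, max_deg=45.0, max_mm=50.0, reference_point=(0.0, 0.0, 0.0)):
    """A random rigid transform with bounded Euler angles and translation."""
    t = rng.uniform(-max_mm, max_mm, size=3)
    r = rng.uniform(-max_deg, max_deg, size=3)
    return euler_to_transform(EulerAngles6D(*t, *r), reference_point)


def chord_mm(angle_deg: float, radius_mm: float) -> float:
    """Displacement of a point at `radius_mm` from the axis of a rotation."""
    return 2.0 * math.sin(math.radians(angle_deg) / 2.0) * radius_mm


@pytest.fixture(scope="session")
def cranial_phantom():
    return build_phantom("cranial", seed=0)


@pytest.fixture(scope="session")
def body_phantom():
    return build_phantom("body", seed=0)


@pytest.fixture
def tetra_clouds():
    """A non-coplanar 4-marker cloud pair related by the identity."""
    pts = np.array([[0.0, 0, 0], [10, 0, 0], [0, 10, 0], [0, 0, 10]])
    a = cloud_from_points(pts, frame="planning-CT")
    b = a.with_positions(pts.copy(), frame="CBCT")
    return a, b
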