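import numpy as np
import pytest

from spinekin import synthetic_spine as ss


@pytest.fixture(scope="session")
def default_template():
    return ss.SpineTemplate()


@pytest.fixture(scope="session")
def resting_pose(default_template):
    return ss.build_template(default_template)


@pytest.fixture(scope="session")
def default_joints():
    return ss.JointConfig()


@pytest.fixture(scope="session")
def vertebra_mesh(default_template):
    """One analytic vertebra in its local frame."""
    return ss.build_vertebra_mesh(default_template)


def random_rigid(rng: np.random.Generator, max_angle_deg: float = 180.0, max_t: float = 50.0):
    """A random proper rigid transform for recovery tests."""
    from spinekin.transforms import RigidTransform, rotation_about_axis

    axis = rng.normal(size=3)
    angle = rng.uniform(-max_angle_deg, max_angle_deg)
    R = rotation_about_axis(axis, angle)
    t = rng.uniform(-max_t, max_t, size=3)
    return RigidTransform(R, t)
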