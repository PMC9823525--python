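import numpy as np
import pytest

import skelkin as sk
from skelkin.model_io import (
    BodyDefinition,
    DegreeOfFreedom,
    GROUND,
    JointDefinition,
    MarkerDefinition,
    SkeletalModel,
)


@pytest.fixture(scope="session")
def default_model():
    return sk.make_default_model()


@pytest.fixture(scope="session")
def planar_arm():
    """Two-link planar arm: link lengths 0.3 m and 0.25 m, z-axis hinges.

    The shoulder sits at the trunk origin; both links point along +x in the
    neutral pose; the end marker sits at the tip of the second link.
    """
    zero = np.zeros(3)
    model = SkeletalModel(
        root_body="trunk",
        bodies=[
            BodyDefinition("trunk", 100.0, long_axis=0),
            BodyDefinition("upper", 300.0, long_axis=0),
            BodyDefinition("lower", 250.0, long_axis=0),
        ],
        joints=[
            JointDefinition(
                "shoulder", "trunk", "upper", zero, zero, zero, zero,
                dofs=[DegreeOfFreedom("shoulder_angle", np.array([0.0, 0.0, 1.0]), (-np.pi, np.pi))],
            ),
            JointDefinition(
                "elbow", "upper", "lower", zero, np.array([0.3, 0.0, 0.0]), zero, zero,
                dofs=[DegreeOfFreedom("elbow_angle", np.array([0.0, 0.0, 1.0]), (-np.pi, np.pi))],
            ),
        ],
        markers=[
            MarkerDefinition("trunk_origin", "trunk", zero, True),
            MarkerDefinition("end", "lower", np.array([0.25, 0.0, 0.0]), True),
        ],
        root_joint=JointDefinition(
            "ground_trunk", GROUND, "trunk", zero, zero, zero, zero,
            dofs=[DegreeOfFreedom("trunk_rotation", np.array([0.0, 0.0, 1.0]), (-np.inf, np.inf))],
        ),
        name="planar_arm",
    )
    return model.validate()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_angles(model, rng, fraction=0.5):
    """Random angles inside every coordinate's declared range."""
    ranges = model.coordinate_ranges()
    lo = np.where(np.isfinite(ranges[:, 0]), ranges[:, 0], -1.0)
    hi = np.where(np.isfinite(ranges[:, 1]), ranges[:, 1], 1.0)
    mid, half = (lo + hi) / 2, (hi - lo) / 2
    return mid + rng.uniform(-fraction, fraction, len(mid)) * half


def random_scales(model, rng, lo=0.85, hi=1.15):
    return sk.BodyScales(list(model.body_names), rng.uniform(lo, hi, (len(model.bodies), 3)))


def random_rotation(rng):
    from scipy.spatial.transform import Rotation

    return Rotation.random(random_state=np.random.RandomState(rng.integers(2**31))).as_matrix()
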