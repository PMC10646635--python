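import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from beach_sij.config import SyntheticConfig
from beach_sij.roi import JointDelineation
from beach_sij.synthetic import generate_patient

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_config() -> SyntheticConfig:
    """A compact cohort configuration used across tests."""
    return SyntheticConfig(n_patients=4, n_slices=6, grid_shape=(96, 96))


@pytest.fixture(scope="session")
def patient(small_config):
    """One fully generated synthetic patient."""
    return generate_patient(small_config, 0)


def straight_delineation(length=40.0, x=30.0, top=10.0, slice_index=0, joint_side="left"):
    """A vertical straight joint with perpendicular anchors."""
    polyline = np.array([[x, top], [x, top + length]])
    a0 = np.array([[x - 4.0, top], [x + 4.0, top]])
    a1 = np.array([[x - 4.0, top + length], [x + 4.0, top + length]])
    return JointDelineation(
        slice_index=slice_index,
        joint_side=joint_side,
        polyline=polyline,
        anchor_start=a0,
        anchor_end=a1,
    )


def random_delineation(rng, joint_side="left"):
    """A random gently-curved delineation within a ~140 mm field of view."""
    n = int(rng.integers(3, 7))
    x0 = rng.uniform(30.0, 80.0)
    top = rng.uniform(15.0, 30.0)
    length = rng.uniform(30.0, 50.0)
    ys = np.linspace(top, top + length, n)
    s = np.linspace(-1, 1, n)
    xs = x0 + rng.uniform(1.0, 4.0) * (1 - s**2) + rng.normal(0, 0.5, n)
    poly = np.column_stack([xs, ys])
    t0 = poly[1] - poly[0]
    t0 = t0 / np.hypot(*t0)
    t1 = poly[-1] - poly[-2]
    t1 = t1 / np.hypot(*t1)

    def rot(v, a):
        c, s_ = np.cos(a), np.sin(a)
        return np.array([c * v[0] - s_ * v[1], s_ * v[0] + c * v[1]])

    d0 = rot(np.array([-t0[1], t0[0]]), rng.normal(0, 0.15))
    d1 = rot(np.array([-t1[1], t1[0]]), rng.normal(0, 0.15))
    return JointDelineation(
        slice_index=0,
        joint_side=joint_side,
        polyline=poly,
        anchor_start=np.array([poly[0] - 4 * d0, poly[0] + 4 * d0]),
        anchor_end=np.array([poly[-1] - 4 * d1, poly[-1] + 4 * d1]),
    )


def point_in_polygon_oracle(xs, ys, ring):
    """Brute-force crossing-number point-in-polygon, independent of shapely.

    ``ring`` is an (n, 2) closed or open vertex array; points exactly on an
    edge are not handled specially (test geometries avoid such ties).
    """
    ring = np.asarray(ring, dtype=float)
    if np.allclose(ring[0], ring[-1]):
        ring = ring[:-1]
    x1, y1 = ring[:, 0], ring[:, 1]
    x2, y2 = np.roll(x1, -1), np.roll(y1, -1)
    xs = np.asarray(xs, dtype=float).ravel()[:, None]
    ys = np.asarray(ys, dtype=float).ravel()[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        crosses = ((y1 > ys) != (y2 > ys)) & (
            xs < (x2 - x1) * (ys - y1) / (y2 - y1) + x1
        )
    return (crosses.sum(axis=1) % 2).astype(bool)
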