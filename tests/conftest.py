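import numpy as np
import pytest

import duplexmd as dm


@pytest.fixture(scope="session")
def duplex():
    """Idealized 13-bp duplex, single frame."""
    return dm.make_duplex(dm.DuplexSpec())


@pytest.fixture(scope="session")
def pair_map():
    return dm.duplex_pair_map(13)


@pytest.fixture(scope="session")
def jittered_traj(duplex):
    """50-frame duplex trajectory with small isotropic jitter."""
    motion = dm.MotionSpec(n_frames=50, dt=10.0, jitter_sigma=0.2, seed=11)
    return dm.make_trajectory(duplex, motion)


@pytest.fixture(scope="session")
def opening_traj(duplex):
    """Terminally-ordered opening: pairs 1-3 open with inward-increasing tau."""
    motion = dm.MotionSpec(
        n_frames=300, dt=10.0, jitter_sigma=0.15, seed=7,
        opening=[dm.OpeningEvent(1, 12.0, 0.2),
                 dm.OpeningEvent(2, 10.0, 0.5),
                 dm.OpeningEvent(3, 8.0, 1.0)])
    return dm.make_trajectory(duplex, motion)


def random_rigid_motion(rng):
    """A uniformly random proper rotation and a translation."""
    from scipy.spatial.transform import Rotation
    R = Rotation.random(rng=rng).as_matrix()
    t = rng.uniform(-20, 20, size=3)
    return R, t


def apply_rigid(coords, R, t):
    """Apply x -> R x + t to (..., 3) coordinates."""
    return coords @ R.T + t


def rigid_copy(traj, R, t):
    """Trajectory with every frame moved by the same rigid motion."""
    return dm.Trajectory(traj.topology, apply_rigid(traj.coords, R, t),
                         dt=traj.dt, t0=traj.t0)
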