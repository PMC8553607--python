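import numpy as np
import pytest

from volgrid import synthetic
from volgrid.containers import RateMap, SpikeTrain, Trajectory


@pytest.fixture(scope="session")
def fcc_ratemap():
    """Axis-aligned simulated FCC arrangement, S = 400 mm, sigma = 2."""
    spec = synthetic.ArrangementSpec("FCC", S=400.0, sigma=2.0, seed=1)
    lat = synthetic.make_arrangement(spec)
    return synthetic.arrangement_ratemap(lat, spec), spec, lat


@pytest.fixture(scope="session")
def volume_session():
    """Dense free-volume walk with spikes from a 3-field rate map."""
    tspec = synthetic.TrajectorySpec(duration=900.0, environment="volume",
                                     mean_speed=15.0, seed=11)
    traj = synthetic.simulate_trajectory(tspec)
    shape = (39, 39, 39)
    voxel = 97.0 / 39.0
    centers = np.array([[25.0, 25.0, 30.0], [70.0, 60.0, 50.0],
                        [40.0, 75.0, 75.0]])
    ax = [(np.arange(s) + 0.5) * voxel for s in shape]
    gx, gy, gz = np.meshgrid(*ax, indexing="ij")
    pts = np.stack([gx, gy, gz], axis=-1)
    rate = np.zeros(shape)
    for c in centers:
        d2 = np.sum((pts - c) ** 2, axis=-1)
        rate += np.exp(-0.5 * d2 / 8.0 ** 2)
    rm = RateMap(rate=rate, occupancy=np.ones(shape), spikes=np.zeros(shape),
                 voxel_size=voxel, origin=np.zeros(3),
                 visited=np.ones(shape, dtype=bool))
    spikes = synthetic.generate_spikes(rm, traj, gain_hz=50.0, seed=12)
    return traj, spikes, rm, centers


@pytest.fixture(scope="session")
def arena_hex_session():
    """Arena walk with spikes from a planar hexagonal firing pattern."""
    tspec = synthetic.TrajectorySpec(duration=600.0, environment="arena",
                                     seed=21)
    traj = synthetic.simulate_trajectory(tspec)
    spec = synthetic.ArrangementSpec("HCP", S=300.0, sigma=2.0, seed=2,
                                     extent=np.array([1200.0, 1200.0, 300.0]))
    layer = synthetic.make_arrangement(spec)
    pts2d = layer.points[layer.layer_index == 0][:, :2] / 10.0  # cm
    nx = ny = 48
    voxel = 120.0 / nx
    ax = (np.arange(nx) + 0.5) * voxel
    gx, gy = np.meshgrid(ax, ax, indexing="ij")
    d2 = np.min((gx[..., None] - pts2d[:, 0]) ** 2 +
                (gy[..., None] - pts2d[:, 1]) ** 2, axis=-1)
    sigma_cm = 2.0 * voxel
    rate2d = np.exp(-0.5 * d2 / sigma_cm ** 2)
    rate3d = rate2d[:, :, None]
    rm = RateMap(rate=rate3d, occupancy=np.ones_like(rate3d),
                 spikes=np.zeros_like(rate3d), voxel_size=voxel,
                 origin=np.zeros(3), visited=np.ones_like(rate3d, dtype=bool))
    spikes = synthetic.generate_spikes(rm, traj, gain_hz=10.0, seed=22)
    return traj, spikes, rate2d


def poisson_spikes(traj: Trajectory, rate_hz: float, seed: int) -> SpikeTrain:
    """Homogeneous Poisson train over the session."""
    rng = np.random.default_rng(seed)
    T = traj.t[-1] - traj.t[0]
    n = rng.poisson(rate_hz * T)
    return SpikeTrain(times=np.sort(traj.t[0] + rng.uniform(0, T, n)))
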