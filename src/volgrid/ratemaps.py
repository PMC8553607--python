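"""Firing-rate map construction and the behavioural filters applied first.

Two estimators are provided.  The adaptive method expands a sphere around
every voxel until ``r > alpha / (n * sqrt(s))`` is met, where ``r`` is the
sphere radius in voxels, ``n`` the tracking samples inside it and ``s``
the spikes; the voxel's rate is then ``(s / n) * sample_rate``.  With the
study constant ``alpha = 1600`` this balances spatial resolution against
sampling noise.  The histogram method bins dwell time and spikes and
smooths both with a Gaussian before dividing.
"""

from __future__ import annotations

from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage, signal

from .containers import RateMap, SpikeTrain, Trajectory

__all__ = [
    "speed_filter",
    "movement_epoch_split",
    "adaptive_ratemap",
    "histogram_ratemap",
    "project_ratemap",
    "spike_positions",
]

PLANES = {"XY": 2, "XZ": 1, "YZ": 0}    # axis collapsed by each projection


def spike_positions(traj: Trajectory, spikes: SpikeTrain) -> np.ndarray:
    """Interpolated position of each spike along the trajectory (cm)."""
    return traj.position_at(spikes.times)


def _spikes_in_samples(traj: Trajectory, spikes: SpikeTrain) -> np.ndarray:
    """Index of the tracking sample whose interval contains each spike."""
    idx = np.searchsorted(traj.t, spikes.times, side="right") - 1
    return np.clip(idx, 0, len(traj.t) - 1)


def _filter_pair(traj: Trajectory, spikes: SpikeTrain, keep: np.ndarray
                 ) -> Tuple[Trajectory, SpikeTrain]:
    spike_keep = keep[_spikes_in_samples(traj, spikes)] if spikes.n else \
        np.zeros(0, dtype=bool)
    return traj.select(keep), SpikeTrain(times=spikes.times[spike_keep],
                                         cell_id=spikes.cell_id)


def speed_filter(traj: Trajectory, spikes: SpikeTrain,
                 min_speed: float = 5.0) -> Tuple[Trajectory, SpikeTrain]:
    """Drop samples (and their spikes) while the animal moved below
    ``min_speed`` cm/s — slow epochs are contaminated by non-locomotor
    activity (rest, grooming, sharp-wave ripples)."""
    return _filter_pair(traj, spikes, traj.speed >= min_speed)


def movement_epoch_split(traj: Trajectory, spikes: SpikeTrain,
                         pitch_deg: float = 30.0) -> dict:
    """Partition a session into vertical (|pitch| > 30°) and horizontal
    movement epochs.  30° splits the heading sphere into two equal-area
    halves (an equatorial belt and two caps), so isotropic headings land
    50/50."""
    vert = np.abs(traj.pitch) > pitch_deg
    return {"vertical": _filter_pair(traj, spikes, vert),
            "horizontal": _filter_pair(traj, spikes, ~vert)}


def _grid_geometry(pos: np.ndarray, voxel: float,
                   bounds: Optional[Sequence[float]]):
    if bounds is None:
        lo = np.floor(pos.min(axis=0) / voxel) * voxel
        hi = pos.max(axis=0)
    else:
        lo = np.asarray(bounds[0], dtype=float)
        hi = np.asarray(bounds[1], dtype=float)
    shape = tuple(max(int(np.ceil((h - l) / voxel - 1e-9)), 1)
                  for l, h in zip(lo, hi))
    return lo, shape


def _bin_index(pos: np.ndarray, origin: np.ndarray, voxel: float, shape):
    idx = np.floor((pos - origin) / voxel).astype(int)
    return np.clip(idx, 0, np.asarray(shape) - 1)


def _histogram(pos, origin, voxel, shape, weights=None):
    idx = np.floor((pos - origin) / voxel).astype(int)
    ok = np.all((idx >= 0) & (idx < np.asarray(shape)), axis=1)
    flat = np.ravel_multi_index(tuple(idx[ok].T), shape)
    w = weights[ok] if weights is not None else None
    return np.bincount(flat, weights=w,
                       minlength=int(np.prod(shape))).reshape(shape).astype(float)


def _sphere_kernel(r: float, ndim: int) -> np.ndarray:
    """Boolean ball of voxel centres within Euclidean distance r."""
    m = int(np.floor(r))
    ax = np.arange(-m, m + 1)
    grids = np.meshgrid(*([ax] * ndim), indexing="ij")
    d2 = sum(g ** 2 for g in grids)
    return d2 <= r * r + 1e-9


def adaptive_ratemap(traj: Trajectory, spikes: SpikeTrain,
                     voxel: float = 2.5, alpha: float = 1600.0,
                     bounds: Optional[Sequence[float]] = None,
                     max_radius: Optional[float] = None) -> RateMap:
    """Adaptively binned volumetric rate map (2.5 cm voxels by default).

    For each voxel the counting sphere grows in 1-voxel steps until
    ``r > alpha / (n * sqrt(s))`` with at least one spike inside; voxels
    where the criterion is never met (within half the volume diagonal, the
    sphere clipped at the boundary) are assigned rate 0.  ``visited``
    marks voxels with any direct occupancy.
    """
    origin, shape = _grid_geometry(traj.pos, voxel, bounds)
    occ = _histogram(traj.pos, origin, voxel, shape)
    total_spikes = spikes.n
    if total_spikes:
        spk = _histogram(spike_positions(traj, spikes), origin, voxel, shape)
    else:
        spk = np.zeros(shape)
    visited = occ > 0

    rate = np.zeros(shape)
    if max_radius is None:
        max_radius = 0.5 * np.linalg.norm(shape)
    sample_rate = traj.sample_rate
    done = np.zeros(shape, dtype=bool)
    r = 1
    while r <= max_radius and not done.all():
        kern = _sphere_kernel(r, 3).astype(float)
        n_r = signal.fftconvolve(occ, kern, mode="same")
        s_r = signal.fftconvolve(spk, kern, mode="same")
        n_r = np.maximum(np.round(n_r), 0)
        s_r = np.maximum(np.round(s_r), 0)
        with np.errstate(divide="ignore", invalid="ignore"):
            crit = (s_r >= 1) & (n_r >= 1) & (r > alpha / (n_r * np.sqrt(s_r)))
        new = crit & ~done
        rate[new] = s_r[new] / n_r[new] * sample_rate
        done |= crit
        r += 1
    # never-satisfied voxels keep rate 0 (e.g. spike-free regions)
    return RateMap(rate=rate, occupancy=occ, spikes=spk, voxel_size=voxel,
                   origin=origin, visited=visited, sample_rate=sample_rate,
                   alpha=alpha, occupancy_unit="samples")


def histogram_ratemap(traj: Trajectory, spikes: SpikeTrain,
                      voxel: float = 10.0, smooth_sd: float = 2.5,
                      ndim: int = 3,
                      bounds: Optional[Sequence[float]] = None,
                      plane: str = "XY") -> RateMap:
    """Histogram rate map: Gaussian-smoothed spike count over smoothed
    dwell time.  Defaults follow the volumetric stability variant (10 cm
    voxels, 2.5-bin s.d.); the planar variant uses 2.5 cm bins with a
    1-bin s.d.  ``plane`` picks the two coordinates kept when ndim == 2.
    """
    if ndim == 2:
        keep = [d for d in range(3) if d != PLANES[plane]]
        pos = traj.pos[:, keep]
        spos = spike_positions(traj, spikes)[:, keep] if spikes.n else \
            np.zeros((0, 2))
        if bounds is not None:
            bounds = (np.asarray(bounds[0])[keep], np.asarray(bounds[1])[keep])
    else:
        pos = traj.pos
        spos = spike_positions(traj, spikes) if spikes.n else np.zeros((0, 3))
    origin, shape = _grid_geometry(pos, voxel, bounds)
    dt = np.r_[np.diff(traj.t), 1.0 / traj.sample_rate]
    dwell = _histogram(pos, origin, voxel, shape, weights=dt)
    spk = _histogram(spos, origin, voxel, shape) if len(spos) else np.zeros(shape)
    if dwell.sum() <= 0:
        raise ValueError("zero dwell everywhere")
    visited = dwell > 0
    if smooth_sd and smooth_sd > 0:
        dwell_s = ndimage.gaussian_filter(dwell, smooth_sd)
        spk_s = ndimage.gaussian_filter(spk, smooth_sd)
    else:
        dwell_s, spk_s = dwell, spk
    with np.errstate(divide="ignore", invalid="ignore"):
        rate = np.where(dwell_s > 0, spk_s / np.maximum(dwell_s, 1e-12), 0.0)
    rate[~visited] = 0.0
    return RateMap(rate=rate, occupancy=dwell, spikes=spk, voxel_size=voxel,
                   origin=origin, visited=visited, sample_rate=traj.sample_rate,
                   occupancy_unit="seconds")


def project_ratemap(map3d: RateMap, plane: str = "XY") -> RateMap:
    """Occupancy-weighted collapse of a 3D map onto a coordinate plane:
    projected rate = Σ(λ·n)/Σn along the orthogonal axis, visited voxels
    only."""
    axis = PLANES[plane]
    occ = np.where(map3d.visited, map3d.occupancy, 0.0)
    num = (map3d.rate * occ).sum(axis=axis)
    den = occ.sum(axis=axis)
    with np.errstate(divide="ignore", invalid="ignore"):
        rate = np.where(den > 0, num / np.maximum(den, 1e-12), 0.0)
    keep = [d for d in range(3) if d != axis]
    return RateMap(rate=rate, occupancy=den,
                   spikes=map3d.spikes.sum(axis=axis), voxel_size=map3d.voxel_size,
                   origin=map3d.origin[keep], visited=den > 0,
                   sample_rate=map3d.sample_rate,
                   occupancy_unit=map3d.occupancy_unit)
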