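"""Core in-memory containers shared across the analysis modules.

Conventions
-----------
* Positions are in centimetres, times in seconds, rates in Hz.
* The spatial origin sits at the environment's minimum corner, z points up.
* Volumetric arrays are indexed ``[ix, iy, iz]`` (x fastest-varying axis
  first); 2D arrays are ``[ix, iy]``.  Voxel intervals are half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "Trajectory",
    "SpikeTrain",
    "RateMap",
    "RateMap3D",
    "Autocorr3D",
    "ScoreSphere",
]


@dataclass
class Trajectory:
    """Timestamped 3D path with derived kinematic quantities.

    ``speed``, ``heading``, ``azimuth`` and ``pitch`` are finite-difference
    quantities assigned to the sample at the start of each step; the final
    sample repeats the previous step.  ``heading`` rows are unit vectors
    (NaN where the animal did not move), ``azimuth`` is the projected
    horizontal direction in radians and ``pitch`` the climb angle in
    degrees within [-90, 90].
    """

    t: np.ndarray
    pos: np.ndarray
    speed: np.ndarray = field(default=None, repr=False)
    heading: np.ndarray = field(default=None, repr=False)
    azimuth: np.ndarray = field(default=None, repr=False)
    pitch: np.ndarray = field(default=None, repr=False)

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.pos = np.asarray(self.pos, dtype=float)
        if self.pos.ndim != 2 or self.pos.shape[1] != 3:
            raise ValueError("pos must be (n, 3)")
        if self.t.shape[0] != self.pos.shape[0]:
            raise ValueError("t and pos length mismatch")
        if self.t.size > 1 and np.any(np.diff(self.t) <= 0):
            raise ValueError("t must be strictly increasing")
        if self.speed is None:
            self._derive()

    def _derive(self):
        n = len(self.t)
        if n < 2:
            self.speed = np.zeros(n)
            self.heading = np.full((n, 3), np.nan)
            self.azimuth = np.full(n, np.nan)
            self.pitch = np.zeros(n)
            return
        d = np.diff(self.pos, axis=0)
        dt = np.diff(self.t)[:, None]
        step = np.linalg.norm(d, axis=1)
        speed = step / dt[:, 0]
        with np.errstate(invalid="ignore", divide="ignore"):
            heading = np.where(step[:, None] > 0, d / step[:, None], np.nan)
        azimuth = np.arctan2(d[:, 1], d[:, 0])
        with np.errstate(invalid="ignore", divide="ignore"):
            pitch = np.degrees(np.arcsin(np.clip(
                np.where(step > 0, d[:, 2] / step, 0.0), -1, 1)))
        # assign step quantities to the leading sample; repeat the last step
        self.speed = np.r_[speed, speed[-1]]
        self.heading = np.vstack([heading, heading[-1]])
        self.azimuth = np.r_[azimuth, azimuth[-1]]
        self.pitch = np.r_[pitch, pitch[-1]]

    @classmethod
    def from_raw(cls, t: np.ndarray, pos: np.ndarray,
                 max_gap_s: float = 1.0,
                 smooth_sd_samples: float = 2.0) -> "Trajectory":
        """Build a trajectory from raw tracking with dropouts.

        NaN position samples inside gaps up to ``max_gap_s`` are linearly
        interpolated; longer gaps stay NaN and their samples are dropped.
        The result is then smoothed with a Gaussian of
        ``smooth_sd_samples`` samples to suppress tracking jitter.
        """
        from scipy.ndimage import gaussian_filter1d

        t = np.asarray(t, dtype=float)
        pos = np.array(pos, dtype=float)
        bad = np.isnan(pos).any(axis=1)
        if bad.any():
            good = np.flatnonzero(~bad)
            if len(good) < 2:
                raise ValueError("too few valid tracking samples")
            for k in range(3):
                pos[bad, k] = np.interp(t[bad], t[good], pos[good, k])
            # re-flag samples inside gaps longer than max_gap_s
            gap_starts = np.flatnonzero(np.diff(good) > 1)
            for gs in gap_starts:
                i0, i1 = good[gs], good[gs + 1]
                if t[i1] - t[i0] > max_gap_s:
                    bad_range = np.arange(i0 + 1, i1)
                    pos[bad_range] = np.nan
        keep = ~np.isnan(pos).any(axis=1)
        t, pos = t[keep], pos[keep]
        if smooth_sd_samples and smooth_sd_samples > 0:
            pos = gaussian_filter1d(pos, smooth_sd_samples, axis=0,
                                    mode="nearest")
        return cls(t=t, pos=pos)

    @property
    def n_samples(self) -> int:
        return len(self.t)

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0]) if len(self.t) > 1 else 0.0

    @property
    def sample_rate(self) -> float:
        if len(self.t) < 2:
            return np.nan
        return 1.0 / float(np.median(np.diff(self.t)))

    def select(self, mask: np.ndarray) -> "Trajectory":
        """Subset samples by boolean mask, keeping the derived quantities
        of the original step structure (no re-differentiation)."""
        return Trajectory(
            t=self.t[mask], pos=self.pos[mask], speed=self.speed[mask],
            heading=self.heading[mask], azimuth=self.azimuth[mask],
            pitch=self.pitch[mask],
        )

    def position_at(self, times: np.ndarray) -> np.ndarray:
        """Linear interpolation of position at arbitrary times."""
        times = np.asarray(times, dtype=float)
        out = np.empty((len(times), 3))
        for k in range(3):
            out[:, k] = np.interp(times, self.t, self.pos[:, k])
        return out


@dataclass
class SpikeTrain:
    """Sorted spike timestamps for one cell."""

    times: np.ndarray
    cell_id: str = "cell"

    def __post_init__(self):
        self.times = np.sort(np.asarray(self.times, dtype=float))

    @property
    def n(self) -> int:
        return len(self.times)


@dataclass
class RateMap:
    """Voxelised firing-rate map (2D or 3D).

    ``occupancy`` holds tracking samples per voxel for adaptively binned
    maps and dwell seconds for histogram maps (``occupancy_unit``).
    ``visited`` marks voxels that satisfy the dwell criterion; ``rate`` is
    zero-filled on unvisited voxels — use :meth:`masked_rate` for NaNs.
    """

    rate: np.ndarray
    occupancy: np.ndarray
    spikes: np.ndarray
    voxel_size: float          # cm
    origin: np.ndarray         # cm, length == ndim
    visited: np.ndarray
    sample_rate: float = 25.0
    alpha: Optional[float] = None
    occupancy_unit: str = "samples"

    def __post_init__(self):
        self.origin = np.asarray(self.origin, dtype=float)

    @property
    def ndim(self) -> int:
        return self.rate.ndim

    @property
    def shape(self):
        return self.rate.shape

    @property
    def peak_rate(self) -> float:
        vals = self.rate[self.visited]
        return float(vals.max()) if vals.size else 0.0

    def masked_rate(self) -> np.ndarray:
        out = np.array(self.rate, dtype=float)
        out[~self.visited] = np.nan
        return out

    def voxel_centers(self):
        """Per-axis voxel-centre coordinates in cm."""
        return [self.origin[k] + (np.arange(self.shape[k]) + 0.5) * self.voxel_size
                for k in range(self.ndim)]


# the volumetric case is the common one in this package
RateMap3D = RateMap


@dataclass
class Autocorr3D:
    """Spatial autocorrelation over integer-voxel lags (2D or 3D).

    ``r`` is the per-lag Pearson correlation over mutually visited voxels
    (NaN where fewer than the minimum number of voxel pairs overlap);
    ``n_overlap`` counts the contributing pairs.  The zero lag sits at the
    array centre ``(s-1)//2`` on every axis (all sides are odd).
    """

    r: np.ndarray
    n_overlap: np.ndarray
    voxel_size: float  # cm per lag step

    @property
    def ndim(self) -> int:
        return self.r.ndim

    @property
    def center(self):
        return tuple((s - 1) // 2 for s in self.r.shape)


@dataclass
class ScoreSphere:
    """HGS / SGS of the central oblique plane for every (pitch, azimuth).

    Pitch is the plane's tilt from the horizontal in degrees (0 =
    horizontal slice), azimuth the compass direction of the tilt.  Score
    maps are (n_pitch, n_azimuth); NaN marks unscorable planes (fewer than
    seven autocorrelogram peaks).
    """

    pitch_deg: np.ndarray
    azimuth_deg: np.ndarray
    hgs: np.ndarray
    sgs: np.ndarray

    @property
    def n_planes(self) -> int:
        return self.hgs.size

    def best_plane(self):
        """(pitch, azimuth) of the maximal finite HGS; ties break toward
        the lowest pitch."""
        h = self.hgs
        if not np.isfinite(h).any():
            raise ValueError("all plane scores undefined")
        best = np.nanmax(h)
        ip, ia = np.argwhere(h == best)[0]  # argwhere scans pitch-major: lowest pitch first
        return float(self.pitch_deg[ip]), float(self.azimuth_deg[ia])

    def plane_normals(self) -> np.ndarray:
        """Unit normals, shape (n_pitch, n_azimuth, 3)."""
        th = np.radians(self.pitch_deg)[:, None]
        ph = np.radians(self.azimuth_deg)[None, :]
        n = np.empty(self.hgs.shape + (3,))
        n[..., 0] = np.sin(th) * np.cos(ph)
        n[..., 1] = np.sin(th) * np.sin(ph)
        n[..., 2] = np.cos(th) * np.ones_like(ph)
        return n
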