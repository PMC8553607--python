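"""Spatial information, sparsity, stability and directional tuning.

Spatial information is the Skaggs measure over a smoothed histogram map
with occupancy probabilities p_i and per-voxel rates λ_i (mean rate λ):

    bits/spike:  Σ p_i (λ_i/λ) log2(λ_i/λ)
    bits/s:      Σ p_i λ_i log2(λ_i/λ)       (= λ · bits/spike)

and sparsity the Skaggs ratio (Σ p_i λ_i)² / Σ p_i λ_i².  Every shuffle
here standardises the observed value against circular spike-train-shift
nulls: z = (observed − μ_shuffle)/σ_shuffle, with z > 1.96 read as
exceeding the shuffle 95th percentile (the package-wide convention).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Dict, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .containers import RateMap, SpikeTrain, Trajectory
from .gridscore import circular_shift
from .ratemaps import histogram_ratemap, spike_positions

__all__ = [
    "InfoStats",
    "spatial_information",
    "ShuffleDistribution",
    "spike_shift_shuffle",
    "split_half_stability",
    "split_half_null",
    "DirectionalTuning",
    "directional_tuning",
    "directional_population_stability",
    "map_correlation",
]


@dataclass
class InfoStats:
    spatial_info: float            # bits/s
    spatial_info_per_spike: float  # bits/spike
    sparsity: float
    mean_rate: float               # Hz


def _info_from_map(ratemap: RateMap) -> InfoStats:
    occ = np.where(ratemap.visited, ratemap.occupancy, 0.0).astype(float)
    total = occ.sum()
    if total <= 0:
        raise ValueError("no occupancy")
    p = occ / total
    lam = np.where(ratemap.visited, ratemap.rate, 0.0)
    mean = float((p * lam).sum())
    if mean <= 0:
        return InfoStats(0.0, 0.0, 1.0, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = lam / mean
        logr = np.zeros_like(ratio)
        np.log2(ratio, out=logr, where=ratio > 0)
    per_spike = float((p * ratio * logr).sum())
    rate_form = float((p * lam * logr).sum())
    sparsity = float(mean ** 2 / (p * lam ** 2).sum())
    return InfoStats(rate_form, per_spike, sparsity, mean)


def spatial_information(traj: Trajectory, spikes: SpikeTrain,
                        voxel: float = 2.0, smooth_sd: float = 2.0,
                        ndim: int = 3, bounds=None) -> InfoStats:
    """Skaggs spatial information and sparsity on a 2 cm histogram map
    smoothed with a 2-voxel Gaussian (see module docstring).  A silent
    cell carries zero information by convention."""
    m = histogram_ratemap(traj, spikes, voxel=voxel, smooth_sd=smooth_sd,
                          ndim=ndim, bounds=bounds)
    return _info_from_map(m)


@dataclass
class ShuffleDistribution:
    observed: float
    values: np.ndarray
    mu: float
    sigma: float
    z: float

    @property
    def significant(self) -> bool:
        """Exceeds the shuffle 95th percentile."""
        return bool(self.observed > np.percentile(self.values, 95))


def spike_shift_shuffle(traj: Trajectory, spikes: SpikeTrain,
                        statistic: Callable[[Trajectory, SpikeTrain], float],
                        n: int = 100, increment: float = 0.02,
                        min_shift: float = 20.0,
                        seed: int = 0) -> ShuffleDistribution:
    """Standardise a statistic against circular spike-train shifts.

    Shifts are drawn uniformly on an ``increment``-second grid with a
    ``min_shift`` floor; the observed value is z-scored against the
    ``n`` shuffle values.
    """
    T = traj.t[-1] - traj.t[0]
    if T <= 2 * min_shift:
        raise ValueError("session too short for the minimum shift")
    rng = np.random.default_rng(seed)
    observed = statistic(traj, spikes)
    n_steps = max(int((T - 2 * min_shift) / increment), 1)
    vals = np.empty(n)
    for i in range(n):
        shift = min_shift + rng.integers(0, n_steps + 1) * increment
        vals[i] = statistic(traj, circular_shift(spikes, traj, shift))
    mu = float(np.nanmean(vals))
    sigma = float(np.nanstd(vals, ddof=1))
    z = (observed - mu) / sigma if sigma > 0 else np.nan
    return ShuffleDistribution(float(observed), vals, mu, sigma, float(z))


def map_correlation(a: RateMap, b: RateMap) -> float:
    """Pearson correlation of two rate maps over mutually visited bins."""
    if a.shape != b.shape:
        raise ValueError("maps must share a grid")
    m = a.visited & b.visited
    if m.sum() < 3:
        return np.nan
    x, y = a.rate[m], b.rate[m]
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return np.nan
    return float(np.corrcoef(x, y)[0, 1])


def _half_maps(traj: Trajectory, spikes: SpikeTrain, map_kind: str, bounds):
    if bounds is None:
        # both halves must share one voxel grid
        lo = np.floor(traj.pos.min(axis=0))
        hi = traj.pos.max(axis=0) + 1e-9
        bounds = (lo, hi)
    t_mid = traj.t[0] + (traj.t[-1] - traj.t[0]) / 2.0
    halves = []
    for sel in (traj.t < t_mid, traj.t >= t_mid):
        sub = traj.select(sel)
        idx = np.searchsorted(traj.t, spikes.times, side="right") - 1
        keep = sel[np.clip(idx, 0, len(traj.t) - 1)]
        st = SpikeTrain(times=spikes.times[keep], cell_id=spikes.cell_id)
        if st.n == 0:
            return None
        if map_kind == "volume":
            halves.append(histogram_ratemap(sub, st, voxel=10.0,
                                            smooth_sd=2.5, bounds=bounds))
        else:
            halves.append(histogram_ratemap(sub, st, voxel=2.5, smooth_sd=1.0,
                                            ndim=2, plane=map_kind,
                                            bounds=bounds))
    return halves


def split_half_stability(traj: Trajectory, spikes: SpikeTrain,
                         map_kind: str = "volume",
                         bounds=None) -> Optional[float]:
    """Within-session stability: Pearson correlation between rate maps of
    the first and second session halves over mutually visited bins.

    ``map_kind`` is 'volume' (10 cm voxels, σ = 2.5 bins) or a projection
    plane 'XY'/'XZ'/'YZ' (2.5 cm bins, σ = 1 bin).  None when either
    half lacks spikes.
    """
    halves = _half_maps(traj, spikes, map_kind, bounds)
    if halves is None:
        return None
    return map_correlation(*halves)


def split_half_null(cells: Sequence[Tuple[Trajectory, SpikeTrain]],
                    map_kind: str = "volume", n_pairs: int = 5000,
                    seed: int = 0, bounds=None) -> np.ndarray:
    """Chance stability: correlate the first half of one cell with the
    second half of a *different* random cell, ``n_pairs`` times."""
    rng = np.random.default_rng(seed)
    halves = [_half_maps(t, s, map_kind, bounds) for t, s in cells]
    halves = [h for h in halves if h is not None]
    if len(halves) < 2:
        raise ValueError("need at least two cells with spikes in both halves")
    out = np.empty(n_pairs)
    for i in range(n_pairs):
        a, b = rng.choice(len(halves), size=2, replace=False)
        out[i] = map_correlation(halves[a][0], halves[b][1])
    return out


@dataclass
class DirectionalTuning:
    bin_centers_deg: np.ndarray
    rate: np.ndarray               # Hz per bin
    occupancy_s: np.ndarray
    rayleigh: float
    preferred_deg: float
    n_spikes: int
    low_n: bool


def directional_tuning(traj: Trajectory, spikes: SpikeTrain,
                       bin_deg: float = 6.0, smooth_sd_bins: float = 3.0,
                       low_n: int = 100) -> DirectionalTuning:
    """Head-azimuth tuning curve in 6° bins.

    Position and spike azimuths are binned, both histograms circularly
    Gaussian-smoothed (σ = 3 bins), and divided to give Hz; the Rayleigh
    vector length of the curve measures directionality and the maximal
    bin gives the preferred direction.  Cells under ``low_n`` spikes are
    flagged.
    """
    nbins = int(round(360.0 / bin_deg))
    edges = np.radians(np.linspace(-180.0, 180.0, nbins + 1))
    az = traj.azimuth
    ok = np.isfinite(az)
    dt = np.r_[np.diff(traj.t), 1.0 / traj.sample_rate]
    occ, _ = np.histogram(az[ok], bins=edges, weights=dt[ok])
    idx = np.clip(np.searchsorted(traj.t, spikes.times, side="right") - 1,
                  0, len(traj.t) - 1)
    saz = az[idx]
    sok = np.isfinite(saz)
    spk, _ = np.histogram(saz[sok], bins=edges)
    occ_s = ndimage.gaussian_filter1d(occ, smooth_sd_bins, mode="wrap")
    spk_s = ndimage.gaussian_filter1d(spk.astype(float), smooth_sd_bins,
                                      mode="wrap")
    with np.errstate(divide="ignore", invalid="ignore"):
        rate = np.where(occ_s > 0, spk_s / np.maximum(occ_s, 1e-12), 0.0)
    centers = np.degrees((edges[:-1] + edges[1:]) / 2.0)
    w = rate.clip(min=0)
    if w.sum() > 0:
        vec = np.sum(w * np.exp(1j * np.radians(centers))) / w.sum()
        rayleigh = float(np.abs(vec))
    else:
        rayleigh = 0.0
    preferred = float(centers[int(np.argmax(rate))])
    return DirectionalTuning(centers, rate, occ, rayleigh, preferred,
                             spikes.n, spikes.n < low_n)


def directional_population_stability(curves_a: np.ndarray,
                                     curves_b: np.ndarray,
                                     n: int = 1000, seed: int = 0) -> Dict:
    """Do cells keep their allocentric preferred directions between
    environments?

    The pooled tuning curves of all cells in one environment are
    correlated against the other's; the null circularly shifts each
    cell's second-environment curve independently by 1–nbins bins.
    Significant when the observed correlation exceeds the null 95th
    percentile; also z-scored.
    """
    a = np.atleast_2d(np.asarray(curves_a, dtype=float))
    b = np.atleast_2d(np.asarray(curves_b, dtype=float))
    if a.shape != b.shape:
        raise ValueError("curve sets must match")
    rng = np.random.default_rng(seed)
    nbins = a.shape[1]

    def pooled_r(bb):
        return float(np.corrcoef(a.ravel(), bb.ravel())[0, 1])

    r_obs = pooled_r(b)
    null = np.empty(n)
    for i in range(n):
        shifts = rng.integers(1, nbins + 1, size=len(b))
        null[i] = pooled_r(np.array([np.roll(row, s)
                                     for row, s in zip(b, shifts)]))
    mu, sd = float(null.mean()), float(null.std(ddof=1))
    z = (r_obs - mu) / sd if sd > 0 else np.nan
    return {"r": r_obs, "null": null, "z": float(z),
            "significant": bool(r_obs > np.percentile(null, 95))}
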