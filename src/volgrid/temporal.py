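"""Spike-train temporal structure: theta modulation and speed coding.

The theta fit models the ±500 ms spike autocorrelogram (10 ms bins,
normalised to its 100–150 ms maximum) as a decaying oscillation

    y(t) = (a·(sin(2πωt + π/2) + 1) + b)·exp(−|t|/τ1) + c·exp(−t²/τ2²)

with ω restricted to the 6–12 Hz theta band; a/b is the modulation
strength.  The speed score is the slope of mean instantaneous firing
rate against running speed in 2 cm/s bins.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional

import numpy as np
from scipy import ndimage, optimize

from .containers import SpikeTrain, Trajectory

__all__ = [
    "spike_autocorrelogram",
    "ThetaFit",
    "theta_fit",
    "SpeedTuning",
    "speed_rate_score",
    "MIN_SPIKES_FOR_FIT",
]

MIN_SPIKES_FOR_FIT = 500


def spike_autocorrelogram(spikes: SpikeTrain, window: float = 0.5,
                          bin_s: float = 0.01,
                          normalize: bool = True) -> Dict[str, np.ndarray]:
    """Histogram of spike-pair lags within ±``window`` s.

    When ``normalize`` is set, counts are divided by the maximum found
    at lags of 100–150 ms and bins exceeding 1 are dropped (NaN), after
    excluding the zero-lag bin — the form the theta fit expects.
    """
    t = spikes.times
    if len(t) < 2:
        raise ValueError("need at least two spikes")
    nbins = int(round(2 * window / bin_s))
    edges = np.linspace(-window, window, nbins + 1)
    # windowed pair search keeps this O(n * mean pairs per window)
    j0 = np.searchsorted(t, t - window, side="left")
    j1 = np.searchsorted(t, t + window, side="right")
    lags = []
    for i in range(len(t)):
        li = t[j0[i]:j1[i]] - t[i]
        lags.append(np.delete(li, i - j0[i]))   # drop the self pair only
    lags = np.concatenate(lags) if lags else np.zeros(0)
    counts, _ = np.histogram(lags, bins=edges)
    counts = counts.astype(float)
    centers = (edges[:-1] + edges[1:]) / 2.0
    out = counts.astype(float)
    if normalize:
        out[np.argmin(np.abs(centers))] = np.nan       # zero-lag bin
        ref = np.abs(centers)
        band = (ref >= 0.1) & (ref <= 0.15)
        peak = np.nanmax(out[band])
        if peak > 0:
            out = out / peak
        out[out > 1] = np.nan
    return {"lag_s": centers, "value": out, "counts": counts}


@dataclass
class ThetaFit:
    a: float
    b: float
    c: float
    omega: float       # Hz
    tau1: float        # s
    tau2: float        # s
    sse: float
    fitted: bool

    @property
    def modulation_strength(self) -> float:
        return self.a / self.b if self.b > 0 else np.inf


def _theta_model(t, a, b, c, omega, tau1, tau2):
    osc = (a * (np.sin(2 * np.pi * omega * t + np.pi / 2) + 1) + b)
    return osc * np.exp(-np.abs(t) / tau1) + c * np.exp(-t ** 2 / tau2 ** 2)


def theta_fit(autocorrelogram: Dict[str, np.ndarray],
              n_spikes: Optional[int] = None) -> ThetaFit:
    """Bounded nonlinear least-squares fit of the theta model.

    Bounds: a, b ≥ 0; c ∈ [0, 0.8]; ω ∈ [6, 12] Hz; τ2 ∈ (0, 0.05] s
    (τ1 is effectively unrestricted).  Cells under 500 spikes are not
    fitted.  The bounded problem is non-convex, so the fit multi-starts
    from five ω initialisations spanning the theta band.
    """
    if n_spikes is not None and n_spikes < MIN_SPIKES_FOR_FIT:
        return ThetaFit(*([np.nan] * 6), np.inf, fitted=False)
    t = autocorrelogram["lag_s"]
    y = autocorrelogram["value"]
    ok = np.isfinite(y)
    t, y = t[ok], y[ok]
    if len(y) < 20:
        return ThetaFit(*([np.nan] * 6), np.inf, fitted=False)
    lo = [0.0, 0.0, 0.0, 6.0, 1e-3, 1e-4]
    hi = [np.inf, np.inf, 0.8, 12.0, 1e3, 0.05]
    best = None
    for w0 in (6.5, 7.25, 8.0, 9.5, 11.0):
        p0 = [0.2, 0.5, 0.0, w0, 0.1, 0.02]
        try:
            popt, _ = optimize.curve_fit(_theta_model, t, y, p0=p0,
                                         bounds=(lo, hi), maxfev=20000)
        except RuntimeError:
            continue
        sse = float(np.sum((y - _theta_model(t, *popt)) ** 2))
        if best is None or sse < best[1]:
            best = (popt, sse)
    if best is None:
        return ThetaFit(*([np.nan] * 6), np.inf, fitted=False)
    p, sse = best
    return ThetaFit(a=float(p[0]), b=float(p[1]), c=float(p[2]),
                    omega=float(p[3]), tau1=float(p[4]), tau2=float(p[5]),
                    sse=sse, fitted=True)


@dataclass
class SpeedTuning:
    bin_edges: np.ndarray      # cm/s
    mean_rate: np.ndarray      # Hz per bin
    time_per_bin: np.ndarray   # s
    slope: float               # Hz/(cm/s)
    intercept: float
    sse: float


def speed_rate_score(traj: Trajectory, spikes: SpikeTrain,
                     speed_bin: float = 2.0, rate_bin_s: float = 0.02,
                     smooth_window_s: float = 0.26,
                     max_speed: Optional[float] = None) -> SpeedTuning:
    """Speed modulation of firing rate.

    Instantaneous rate is the 20 ms spike histogram smoothed with a
    260 ms Gaussian window; speeds are binned in 2 cm/s increments and
    the mean rate per occupied bin is fitted with a least-squares line.
    """
    t0, t1 = traj.t[0], traj.t[-1]
    edges_t = np.arange(t0, t1 + rate_bin_s, rate_bin_s)
    counts, _ = np.histogram(spikes.times, bins=edges_t)
    sd_bins = smooth_window_s / rate_bin_s / 6.0   # window == ±3 sd
    rate = ndimage.gaussian_filter1d(counts / rate_bin_s, sd_bins)
    centers_t = (edges_t[:-1] + edges_t[1:]) / 2.0
    speed = np.interp(centers_t, traj.t, traj.speed)

    if max_speed is None:
        max_speed = np.nanmax(speed)
    edges_v = np.arange(0.0, max_speed + speed_bin, speed_bin)
    which = np.digitize(speed, edges_v) - 1
    nb = len(edges_v) - 1
    mean_rate = np.full(nb, np.nan)
    time_per = np.zeros(nb)
    for b in range(nb):
        m = which == b
        time_per[b] = m.sum() * rate_bin_s
        if m.any():
            mean_rate[b] = rate[m].mean()
    occ = np.isfinite(mean_rate) & (time_per > 0)
    if occ.sum() < 2:
        return SpeedTuning(edges_v, mean_rate, time_per, np.nan, np.nan,
                           np.nan)
    x = (edges_v[:-1] + edges_v[1:])[occ] / 2.0
    y = mean_rate[occ]
    slope, intercept = np.polyfit(x, y, 1)
    sse = float(np.sum((y - (slope * x + intercept)) ** 2))
    return SpeedTuning(edges_v, mean_rate, time_per, float(slope),
                       float(intercept), sse)
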