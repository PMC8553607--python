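"""Hexagonal and square gridness scores and their significance machinery.

The hexagonal gridness score (HGS) of a 2D autocorrelogram is the
rotational-correlation contrast of an annulus enclosing the six firing
peaks nearest the centre:

    HGS = min corr(60°, 120°) − max corr(30°, 90°, 150°)

and the square gridness score (SGS) the fourfold analogue:

    SGS = min corr(90°, 180°) − max corr(45°, 135°, 225°).

Significance uses the bootstrap-versus-shuffle approach: the statistic's
median over spike resamples must exceed the 95th percentile of circular
spike-train-shift shuffles.

`score_slices` evaluates whole stacks of slices at once — rotating the
stack in a single C call per angle — which is what makes the 4,225-plane
planar-symmetry sweep tractable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, List, Optional, Tuple

import numpy as np
from scipy import ndimage

from .containers import Autocorr3D, SpikeTrain, Trajectory

__all__ = [
    "GridScoreResult",
    "ShuffleSignificance",
    "grid_scores_2d",
    "hgs",
    "sgs",
    "score_slices",
    "bootstrap_vs_shuffle",
    "grid_cell_criterion",
    "circular_shift",
]

HGS_ON = (60.0, 120.0)
HGS_OFF = (30.0, 90.0, 150.0)
SGS_ON = (90.0, 180.0)
SGS_OFF = (45.0, 135.0, 225.0)
ALL_ANGLES = tuple(sorted(set(HGS_ON + HGS_OFF + SGS_ON + SGS_OFF)))

PEAK_THRESHOLD = 0.3
MIN_ANNULUS_PIXELS = 20


@dataclass
class GridScoreResult:
    """HGS/SGS of one autocorrelogram annulus; ``scorable`` is False when
    fewer than seven super-threshold peaks exist."""

    hgs: float
    sgs: float
    annulus_inner: float = np.nan
    annulus_outer: float = np.nan
    peak_centers: List[Tuple[float, float]] = field(default_factory=list)
    rotations_used: Tuple[float, ...] = ALL_ANGLES
    scorable: bool = True


def _annulus_params(sl: np.ndarray, threshold: float = PEAK_THRESHOLD):
    """Find the 7 most central peaks of one slice; return
    (r_inner, r_outer, peak_centers) or None if unscorable."""
    mask = np.nan_to_num(sl, nan=-np.inf) > threshold
    lab, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    if n < 7:
        return None
    flat = lab.ravel()
    counts = np.bincount(flat)
    ii, jj = np.indices(sl.shape)
    ci = np.bincount(flat, weights=ii.ravel())[1:] / counts[1:]
    cj = np.bincount(flat, weights=jj.ravel())[1:] / counts[1:]
    c0 = (np.asarray(sl.shape) - 1) / 2.0
    d = np.hypot(ci - c0[0], cj - c0[1])
    order = np.argsort(d)
    central, ring = order[0], order[1:7]
    r_c = np.sqrt(counts[1:][central] / np.pi)
    r_in = max(d[ring].min() - r_c, r_c)
    r_out = d[ring].max() + r_c
    if r_out <= r_in:
        return None
    centers = [(ci[k] - c0[0], cj[k] - c0[1]) for k in ring]
    return float(r_in), float(r_out), centers


def _rotated_gather(h: int, w: int, angle_deg: float):
    """Bilinear resampling plan for an in-plane rotation about the array
    centre: flat source indices and weights, plus an out-of-bounds mask.
    The plan is geometry-only, so one plan serves every slice in a stack.
    """
    ii, jj = np.indices((h, w), dtype=float)
    c0, c1 = (h - 1) / 2.0, (w - 1) / 2.0
    th = np.radians(angle_deg)
    ci, cj = ii - c0, jj - c1
    si = c0 + np.cos(th) * ci - np.sin(th) * cj
    sj = c1 + np.sin(th) * ci + np.cos(th) * cj
    i0 = np.floor(si).astype(int)
    j0 = np.floor(sj).astype(int)
    fi, fj = si - i0, sj - j0
    oob = (i0 < 0) | (i0 > h - 2) | (j0 < 0) | (j0 > w - 2)
    i0c = np.clip(i0, 0, h - 2)
    j0c = np.clip(j0, 0, w - 2)
    base = (i0c * w + j0c).ravel()
    idx = np.stack([base, base + 1, base + w, base + w + 1])
    wts = np.stack([((1 - fi) * (1 - fj)).ravel(), ((1 - fi) * fj).ravel(),
                    (fi * (1 - fj)).ravel(), (fi * fj).ravel()])
    return idx, wts, oob.ravel()


def score_slices(stack: np.ndarray, threshold: float = PEAK_THRESHOLD):
    """HGS and SGS for every slice of a (n, h, w) stack.

    Returns (hgs, sgs, results) with NaN for unscorable slices (fewer
    than seven peaks).  Rotational correlations are evaluated for all
    scorable slices at once: each offset angle contributes one shared
    bilinear-gather plan and a batch of per-slice Pearson correlations
    over the annulus pixels valid in both copies.
    """
    stack = np.asarray(stack, dtype=float)
    n, h, w = stack.shape
    r_in = np.full(n, np.nan)
    r_out = np.full(n, np.nan)
    results: List[GridScoreResult] = []
    for k in range(n):
        p = _annulus_params(stack[k], threshold)
        if p is None:
            results.append(GridScoreResult(np.nan, np.nan, scorable=False))
        else:
            r_in[k], r_out[k] = p[0], p[1]
            results.append(GridScoreResult(np.nan, np.nan, p[0], p[1], p[2]))

    hgs_v = np.full(n, np.nan)
    sgs_v = np.full(n, np.nan)
    keep = np.flatnonzero(np.isfinite(r_in))
    if keep.size == 0:
        return hgs_v, sgs_v, results

    # float32 batch arithmetic: the Pearson sums run over <= a few
    # thousand annulus pixels, so single precision is ample for scores
    sub = stack[keep].reshape(len(keep), -1).astype(np.float32)
    ii, jj = np.indices((h, w))
    c0 = (np.array([h, w]) - 1) / 2.0
    dist = np.hypot(ii - c0[0], jj - c0[1]).ravel()
    annulus = (dist[None, :] >= r_in[keep, None]) & \
              (dist[None, :] <= r_out[keep, None]) & np.isfinite(sub)

    corrs = {}
    rot = np.empty_like(sub)
    tmp = np.empty_like(sub)
    for ang in ALL_ANGLES:
        idx, wts, oob = _rotated_gather(h, w, ang)
        wts = wts.astype(np.float32)
        np.take(sub, idx[0], axis=1, out=rot)
        rot *= wts[0]
        for k in (1, 2, 3):
            np.take(sub, idx[k], axis=1, out=tmp)
            tmp *= wts[k]
            rot += tmp
        rot[:, oob] = np.nan
        valid = annulus & np.isfinite(rot)   # NaN sources propagate through
        a = np.where(valid, sub, np.float32(0.0))
        b = np.where(valid, rot, np.float32(0.0))
        npix = valid.sum(axis=1).astype(np.float64)
        sx = a.sum(axis=1, dtype=np.float64)
        sy = b.sum(axis=1, dtype=np.float64)
        sxx = np.einsum("ij,ij->i", a, a, dtype=np.float64)
        syy = np.einsum("ij,ij->i", b, b, dtype=np.float64)
        sxy = np.einsum("ij,ij->i", a, b, dtype=np.float64)
        var1 = npix * sxx - sx * sx
        var2 = npix * syy - sy * sy
        with np.errstate(invalid="ignore", divide="ignore"):
            c = (npix * sxy - sx * sy) / np.sqrt(np.maximum(var1, 0) *
                                                 np.maximum(var2, 0))
        c[(npix < MIN_ANNULUS_PIXELS) | (var1 <= 0) | (var2 <= 0)] = np.nan
        corrs[ang] = c

    hgs_k = np.minimum(corrs[60.0], corrs[120.0]) - \
        np.maximum(np.maximum(corrs[30.0], corrs[90.0]), corrs[150.0])
    sgs_k = np.minimum(corrs[90.0], corrs[180.0]) - \
        np.maximum(np.maximum(corrs[45.0], corrs[135.0]), corrs[225.0])
    hgs_v[keep] = hgs_k
    sgs_v[keep] = sgs_k
    for k, res in enumerate(results):
        res.hgs, res.sgs = float(hgs_v[k]), float(sgs_v[k])
    return hgs_v, sgs_v, results


def grid_scores_2d(ac2d) -> GridScoreResult:
    """Both gridness scores of one 2D autocorrelogram (array or
    :class:`Autocorr3D` with ndim == 2)."""
    arr = ac2d.r if isinstance(ac2d, Autocorr3D) else np.asarray(ac2d, float)
    if arr.ndim != 2:
        raise ValueError("expected a 2D autocorrelogram")
    _, _, results = score_slices(arr[None])
    return results[0]


def hgs(ac2d) -> GridScoreResult:
    """Hexagonal gridness score (see module docstring)."""
    return grid_scores_2d(ac2d)


def sgs(ac2d) -> GridScoreResult:
    """Square gridness score (see module docstring)."""
    return grid_scores_2d(ac2d)


def circular_shift(spikes: SpikeTrain, traj: Trajectory,
                   shift: float) -> SpikeTrain:
    """Circularly time-shift a spike train within the session bounds."""
    t0, t1 = traj.t[0], traj.t[-1]
    T = t1 - t0
    shifted = t0 + np.mod(spikes.times - t0 + shift, T)
    return SpikeTrain(times=shifted, cell_id=spikes.cell_id)


@dataclass
class ShuffleSignificance:
    """Bootstrap-versus-shuffle outcome for one spatial statistic."""

    bootstrap_median: float
    shuffle_values: np.ndarray
    percentile_95: float
    significant: Optional[bool]     # None when the statistic mostly failed
    bootstrap_values: np.ndarray = field(default=None, repr=False)


def bootstrap_vs_shuffle(traj: Trajectory, spikes: SpikeTrain,
                         statistic: Callable[[Trajectory, SpikeTrain], float],
                         n: int = 100, seed: int = 0,
                         min_shift: float = 20.0,
                         increment: float = 0.02) -> ShuffleSignificance:
    """Is a statistic larger than chance?

    Bootstrap: resample spikes with replacement ``n`` times and take the
    median statistic.  Null: circularly shift the spike train by a random
    amount ≥ ``min_shift`` s (drawn on an ``increment``-s grid) ``n``
    times.  Significant iff the bootstrap median exceeds the shuffle 95th
    percentile.  If the statistic fails (NaN) on more than half of either
    set, significance is undefined (None).
    """
    rng = np.random.default_rng(seed)
    T = traj.t[-1] - traj.t[0]
    if T <= 2 * min_shift:
        raise ValueError("session too short for the minimum shift")

    boot = np.empty(n)
    for i in range(n):
        resampled = SpikeTrain(times=rng.choice(spikes.times, size=spikes.n,
                                                replace=True),
                               cell_id=spikes.cell_id)
        boot[i] = statistic(traj, resampled)

    n_steps = int((T - 2 * min_shift) / increment)
    shuf = np.empty(n)
    for i in range(n):
        shift = min_shift + rng.integers(0, max(n_steps, 1) + 1) * increment
        shuf[i] = statistic(traj, circular_shift(spikes, traj, shift))

    ok_boot = np.isfinite(boot)
    ok_shuf = np.isfinite(shuf)
    if ok_boot.mean() < 0.5 or ok_shuf.mean() < 0.5:
        return ShuffleSignificance(np.nan, shuf, np.nan, None, boot)
    med = float(np.median(boot[ok_boot]))
    p95 = float(np.percentile(shuf[ok_shuf], 95))
    return ShuffleSignificance(med, shuf, p95, bool(med > p95), boot)


def grid_cell_criterion(session_pair) -> bool:
    """Grid-cell inclusion: HGS significant in *both* arena sessions."""
    a, b = session_pair
    return bool(a.significant) and bool(b.significant)
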