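"""3D firing-field detection, shape and distribution statistics.

Fields are connected regions (26-connectivity) of an adaptively binned
volumetric rate map exceeding 30% of the map peak, spanning more than 64
voxels, with peak rate above 1 Hz and more than five trajectory visits.
Shape comes from the ellipsoid sharing the region's normalised second
central moments; the elongation index P1 / (0.5·(P2 + P3)) is 1 for a
sphere.  Field-level null models include an in-place field-position
shuffle that preserves the rate-value multiset exactly, a spike-respray
elongation shuffle, and Monte-Carlo axis/layer occupancy tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError, cKDTree
from skimage.morphology import h_maxima
from skimage.segmentation import watershed

from .containers import RateMap, SpikeTrain, Trajectory
from .gridscore import circular_shift
from .ratemaps import adaptive_ratemap, histogram_ratemap, spike_positions

__all__ = [
    "Field",
    "FieldSet",
    "detect_fields",
    "field_axes",
    "elongation_index",
    "equivalent_diameter",
    "elongation_shuffle",
    "orientation_axis_test",
    "vmf_density",
    "field_shuffle",
    "FieldShuffleMap",
    "interfield_cv",
    "layer_distribution_test",
    "fields_per_m3",
    "field_size_cv",
]

DETECT_THRESHOLD = 0.30     # fraction of map peak
MIN_FIELD_VOXELS = 64
MIN_PEAK_RATE = 1.0         # Hz
MIN_VISITS = 5

_STRUCT26 = ndimage.generate_binary_structure(3, 3)


@dataclass
class Field:
    """One detected 3D firing field."""

    voxels: np.ndarray                 # (k, 3) integer voxel indices
    centroid: np.ndarray               # cm
    volume: float                      # cm^3
    convex_volume: float               # cm^3
    peak_rate: float                   # Hz
    visits: int
    principal_axes: np.ndarray = None  # (P1, P2, P3) lengths, cm
    eigenvectors: np.ndarray = None    # columns, unit 3-vectors
    elongation: float = np.nan
    label: int = 0

    @property
    def equivalent_diameter(self) -> float:
        return equivalent_diameter(self.convex_volume)


@dataclass
class FieldSet:
    fields: List[Field] = dc_field(default_factory=list)
    ratemap: Optional[RateMap] = None

    def __len__(self):
        return len(self.fields)

    def __iter__(self):
        return iter(self.fields)

    def __getitem__(self, i):
        return self.fields[i]

    @property
    def volumes(self) -> np.ndarray:
        return np.array([f.volume for f in self.fields])

    @property
    def centroids(self) -> np.ndarray:
        return np.array([f.centroid for f in self.fields]).reshape(-1, 3)


def _count_visits(traj: Trajectory, in_field: np.ndarray,
                  merge_gap_s: float = 1.0) -> int:
    """A visit is a maximal run of in-field samples; runs separated by
    less than ``merge_gap_s`` are merged into one visit."""
    if not in_field.any():
        return 0
    idx = np.flatnonzero(in_field)
    times = traj.t[idx]
    breaks = np.flatnonzero(np.diff(times) >= merge_gap_s)
    return len(breaks) + 1


def field_axes(voxels: np.ndarray, voxel_size: float
               ) -> Tuple[np.ndarray, np.ndarray]:
    """Principal axis lengths and eigenvectors of the ellipsoid with the
    region's normalised second central moments.

    Lengths follow the moment-ellipsoid convention P_i = 4·sqrt(eig_i)
    of the voxel-coordinate covariance (the eigenvalue-to-diameter map of
    a solid ellipsoid, whose variance along a semi-axis a is a²/5 — the
    constant cancels in every ratio used downstream); a planar or
    degenerate region raises ValueError.
    """
    pts = np.asarray(voxels, dtype=float)
    if len(pts) < 4:
        raise ValueError("need >= 4 voxels for 3D axes")
    cov = np.cov(pts.T, bias=True)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    if evals[-1] <= 1e-9:
        raise ValueError("degenerate (planar) field")
    lengths = 4.0 * np.sqrt(evals) * voxel_size
    return lengths, evecs


def elongation_index(principal_axes: Sequence[float], dims: int = 3) -> float:
    """P1 / (0.5·(P2 + P3)) in 3D; P1/P2 in 2D (arena). 1 = sphere."""
    p = np.sort(np.asarray(principal_axes, dtype=float))[::-1]
    if dims == 2:
        return float(p[0] / p[1])
    return float(p[0] / (0.5 * (p[1] + p[2])))


def equivalent_diameter(convex_volume: float) -> float:
    """Diameter of the sphere whose volume equals ``convex_volume``:
    (6·vf/π)^(1/3)."""
    return float((6.0 * convex_volume / np.pi) ** (1.0 / 3.0))


def _convex_volume(pts_cm: np.ndarray, voxel_volume: float) -> float:
    try:
        return float(ConvexHull(pts_cm).volume)
    except (QhullError, ValueError):
        return float(len(pts_cm) * voxel_volume)


def detect_fields(ratemap: RateMap, traj: Optional[Trajectory] = None,
                  threshold: float = DETECT_THRESHOLD,
                  min_voxels: int = MIN_FIELD_VOXELS,
                  min_peak: float = MIN_PEAK_RATE,
                  min_visits: int = MIN_VISITS) -> FieldSet:
    """Detect 3D firing fields in an adaptively binned map.

    Keeps 26-connected regions above ``threshold`` × map peak with more
    than ``min_voxels`` voxels, peak rate above ``min_peak`` Hz and, when
    a trajectory is supplied, more than ``min_visits`` visits.
    """
    out = FieldSet(ratemap=ratemap)
    peak = float(ratemap.rate.max())
    if peak <= 0:
        return out
    # adaptive maps are defined wherever the expansion criterion was met,
    # beyond directly occupied voxels — fields are detected on the full
    # rate volume (undefined voxels carry rate 0 and never pass threshold)
    mask = ratemap.rate > threshold * peak
    lab, n = ndimage.label(mask, structure=_STRUCT26)
    sample_label = None
    if traj is not None:
        vox_idx = np.floor((traj.pos - ratemap.origin) /
                           ratemap.voxel_size).astype(int)
        inside = np.all((vox_idx >= 0) & (vox_idx < np.asarray(ratemap.shape)),
                        axis=1)
        sample_label = np.zeros(len(vox_idx), dtype=int)
        sample_label[inside] = lab[tuple(vox_idx[inside].T)]
    vv = ratemap.voxel_size ** 3
    for k in range(1, n + 1):
        vox = np.argwhere(lab == k)
        if len(vox) <= min_voxels:
            continue
        rates = ratemap.rate[tuple(vox.T)]
        if rates.max() <= min_peak:
            continue
        visits = 0
        if sample_label is not None:
            visits = _count_visits(traj, sample_label == k)
            if visits <= min_visits:
                continue
        pts_cm = ratemap.origin + (vox + 0.5) * ratemap.voxel_size
        f = Field(voxels=vox,
                  centroid=pts_cm.mean(axis=0),
                  volume=len(vox) * vv,
                  convex_volume=_convex_volume(pts_cm, vv),
                  peak_rate=float(rates.max()),
                  visits=visits, label=k)
        try:
            f.principal_axes, f.eigenvectors = field_axes(vox, ratemap.voxel_size)
            f.elongation = elongation_index(f.principal_axes)
        except ValueError:
            pass
        out.fields.append(f)
    return out


def elongation_shuffle(field: Field, traj: Trajectory, spikes: SpikeTrain,
                       ratemap: RateMap, n: int = 100, seed: int = 0,
                       sd_factor: float = 1.8) -> Dict[str, float]:
    """Is a field more elongated than an underlying spherical field would
    produce?

    The field's spikes are resprayed ``n`` times around its centroid with
    an isotropic Gaussian whose s.d. is the equivalent-sphere radius
    divided by 1.8 — a Gaussian thresholded at ~20% of peak spans
    sqrt(2 ln 5) ≈ 1.8 standard deviations, so the resprayed cloud
    reproduces a spherical field with the *same equivalent diameter* as
    the observed one.  Each respray snaps spikes to the nearest
    trajectory point; the local rate map and its elongation are
    recomputed per respray and the observed elongation is z-scored
    against them (z > 1.96 → nonspherical).
    """
    rng = np.random.default_rng(seed)
    spos = spike_positions(traj, spikes)
    vox = np.floor((spos - ratemap.origin) / ratemap.voxel_size).astype(int)
    inside = np.all((vox >= 0) & (vox < np.asarray(ratemap.shape)), axis=1)
    fmask = np.zeros(ratemap.shape, dtype=bool)
    fmask[tuple(field.voxels.T)] = True
    in_field = np.zeros(len(spos), dtype=bool)
    in_field[inside] = fmask[tuple(vox[inside].T)]
    if not in_field.any():
        raise ValueError("field contains no spikes")

    radius = field.equivalent_diameter / 2.0
    sd = radius / sd_factor
    # "trajectories through this sphere": candidate points near the field
    d2 = np.sum((traj.pos - field.centroid) ** 2, axis=1)
    cand = traj.pos[d2 <= (1.5 * radius) ** 2]
    if len(cand) < 10:
        cand = traj.pos
    tree = cKDTree(cand)

    # local crop around the field keeps the respray maps cheap
    pad = int(np.ceil(2.5 * radius / ratemap.voxel_size)) + 2
    lo = np.maximum(field.voxels.min(axis=0) - pad, 0)
    hi = np.minimum(field.voxels.max(axis=0) + pad + 1,
                    np.asarray(ratemap.shape))
    lo_cm = ratemap.origin + lo * ratemap.voxel_size
    hi_cm = ratemap.origin + hi * ratemap.voxel_size
    box = np.all((traj.pos >= lo_cm) & (traj.pos < hi_cm), axis=1)
    sub_traj = traj.select(box)
    if sub_traj.n_samples < 10:
        raise ValueError("too few trajectory samples around the field")
    sub_tree = cKDTree(sub_traj.pos)
    n_spk = int(in_field.sum())

    def local_elongation(spk_times) -> float:
        st = SpikeTrain(times=spk_times, cell_id=spikes.cell_id)
        m = adaptive_ratemap(sub_traj, st, voxel=ratemap.voxel_size,
                             alpha=ratemap.alpha or 1600.0,
                             bounds=(lo_cm, hi_cm))
        fs = detect_fields(m, traj=None, min_voxels=8, min_visits=0)
        if len(fs) == 0:
            return np.nan
        d = np.linalg.norm(fs.centroids - field.centroid, axis=1)
        return fs[int(np.argmin(d))].elongation

    vals = np.empty(n)
    for i in range(n):
        offs = rng.normal(scale=sd, size=(n_spk, 3))
        _, nearest = tree.query(field.centroid + offs)
        pos = cand[nearest]
        # spike times fabricated at the trajectory samples nearest the
        # respray positions (only positions matter for the map)
        _, traj_idx = sub_tree.query(pos)
        new_times = sub_traj.t[traj_idx] + rng.uniform(
            0, 1.0 / sub_traj.sample_rate, n_spk)
        vals[i] = local_elongation(np.sort(new_times))

    ok = np.isfinite(vals)
    mu = float(np.mean(vals[ok])) if ok.any() else np.nan
    sd_s = float(np.std(vals[ok], ddof=1)) if ok.sum() > 1 else np.nan
    z = (field.elongation - mu) / sd_s if sd_s and np.isfinite(sd_s) else np.nan
    return {"observed": field.elongation, "shuffle_mean": mu,
            "shuffle_sd": sd_s, "z": float(z),
            "nonspherical": bool(np.isfinite(z) and z > 1.96)}


def orientation_axis_test(fieldset: FieldSet, n_mc: int = 1000,
                          seed: int = 0, cap_deg: float = 30.0) -> Dict:
    """Are field principal axes over-aligned with the Cartesian axes?

    Axis vectors and their antipodes live on the unit sphere; per
    Cartesian axis, fields within the two 30°-half-angle caps (≈13.4% of
    the sphere by area) are counted and compared with Monte-Carlo uniform
    samples; counts outside the 2.5th–97.5th percentile band are flagged.
    """
    vecs = np.array([f.eigenvectors[:, 0] for f in fieldset
                     if f.eigenvectors is not None]).reshape(-1, 3)
    nf = len(vecs)
    cos_cap = np.cos(np.radians(cap_deg))
    counts = {}
    for k, name in enumerate("xyz"):
        counts[name] = int((np.abs(vecs[:, k]) >= cos_cap).sum()) if nf else 0
    rng = np.random.default_rng(seed)
    mc = np.empty((n_mc, 3))
    for i in range(n_mc):
        v = rng.normal(size=(max(nf, 1), 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        mc[i] = (np.abs(v) >= cos_cap).sum(axis=0)
    lo, hi = np.percentile(mc, [2.5, 97.5], axis=0)
    out = {"n_fields": nf, "chance_fraction": 1.0 - cos_cap}
    for k, name in enumerate("xyz"):
        out[name] = {"count": counts[name],
                     "chance_interval": (float(lo[k]), float(hi[k])),
                     "flagged": bool(counts[name] < lo[k] or
                                     counts[name] > hi[k])}
    return out


def vmf_density(vectors: np.ndarray, sigma_deg: float = 10.0,
                n_grid: int = 60) -> Dict[str, np.ndarray]:
    """von Mises–Fisher-style kernel density of unit vectors on a sphere
    grid; the kernel is exp(−0.5·(x/σ)²) of the great-circle angle x in
    degrees (σ = 10 by default)."""
    vectors = np.atleast_2d(np.asarray(vectors, dtype=float))
    vectors = vectors / np.linalg.norm(vectors, axis=1, keepdims=True)
    az = np.linspace(0, 2 * np.pi, 2 * n_grid, endpoint=False)
    el = np.linspace(-np.pi / 2, np.pi / 2, n_grid)
    AZ, EL = np.meshgrid(az, el, indexing="ij")
    grid = np.stack([np.cos(EL) * np.cos(AZ), np.cos(EL) * np.sin(AZ),
                     np.sin(EL)], axis=-1)
    dots = np.clip(grid @ vectors.T, -1.0, 1.0)
    ang = np.degrees(np.arccos(dots))
    dens = np.exp(-0.5 * (ang / sigma_deg) ** 2).sum(axis=-1)
    return {"azimuth": az, "elevation": el, "density": dens, "grid": grid}


@dataclass
class FieldShuffleMap:
    """Rate volume with field positions shuffled in place."""

    rate: np.ndarray
    field_id: np.ndarray           # provenance: watershed field per voxel
    source: RateMap

    def as_ratemap(self) -> RateMap:
        return RateMap(rate=self.rate, occupancy=self.source.occupancy,
                       spikes=self.source.spikes,
                       voxel_size=self.source.voxel_size,
                       origin=self.source.origin,
                       visited=self.source.visited,
                       sample_rate=self.source.sample_rate,
                       alpha=self.source.alpha,
                       occupancy_unit=self.source.occupancy_unit)


def field_shuffle(ratemap: RateMap, seed: int = 0,
                  oversmooth_sd: float = 3.0, h: float = 0.2
                  ) -> FieldShuffleMap:
    """Shuffle field positions within a rate map while preserving each
    field's internal structure and the map's value multiset exactly.

    An oversmoothed copy (Gaussian σ = 3 bins) is watershed-segmented
    from H-maxima peaks (H = 0.2) on the distance transform; each
    segment's peak bin moves to a uniform random visited position, then
    the remaining bins are moved iteratively (fields cycled in order) to
    the free visited position nearest their ideal offset-from-peak in
    city-block distance.  Unvisited bins keep their positions, so the
    sampling geometry is preserved too.
    """
    vis = ratemap.visited
    rate = ratemap.rate
    rng = np.random.default_rng(seed)

    smoothed = ndimage.gaussian_filter(np.where(vis, rate, 0.0), oversmooth_sd)
    peaks = h_maxima(smoothed, h)
    peak_lab, n_fields = ndimage.label(peaks, structure=_STRUCT26)
    if n_fields == 0 or vis.sum() == 0:
        return FieldShuffleMap(rate=rate.copy(),
                               field_id=np.zeros_like(peak_lab),
                               source=ratemap)
    dist = ndimage.distance_transform_edt(~peaks)
    seg = watershed(dist, markers=peak_lab)
    field_id = np.where(vis, seg, 0)

    out_rate = np.where(vis, np.nan, rate).astype(float)
    out_flat = out_rate.ravel()
    vis_flat = np.flatnonzero(vis.ravel())
    free = np.zeros(rate.size, dtype=bool)
    free[vis_flat] = True
    shape = np.asarray(rate.shape)

    # per field: bins ordered by city-block distance to the field's peak
    orders, peaks_idx, new_peaks = [], [], []
    targets = rng.choice(vis_flat, size=n_fields, replace=False)
    for k in range(1, n_fields + 1):
        bins = np.argwhere((seg == k) & vis)
        rates_k = rate[tuple(bins.T)]
        p = bins[int(np.argmax(rates_k))]
        order = np.argsort(np.abs(bins - p).sum(axis=1), kind="stable")
        orders.append(bins[order])
        peaks_idx.append(p)
        new_peaks.append(np.array(np.unravel_index(targets[k - 1], rate.shape)))

    pointers = [0] * n_fields
    remaining = sum(len(o) for o in orders)
    free_list = np.flatnonzero(free)
    free_coords = np.column_stack(np.unravel_index(free_list, rate.shape))
    while remaining:
        for k in range(n_fields):
            if pointers[k] >= len(orders[k]):
                continue
            b = orders[k][pointers[k]]
            pointers[k] += 1
            remaining -= 1
            ideal = np.clip(new_peaks[k] + (b - peaks_idx[k]), 0, shape - 1)
            ideal_flat = int(np.ravel_multi_index(ideal, rate.shape))
            if free[ideal_flat]:
                tgt = ideal_flat
            else:
                alive = free[free_list]
                if not alive.all():
                    free_list = free_list[alive]
                    free_coords = free_coords[alive]
                d = np.abs(free_coords - ideal).sum(axis=1)
                tgt = int(free_list[int(np.argmin(d))])  # raster tie-break
            out_flat[tgt] = rate[tuple(b)]
            free[tgt] = False
    out = out_flat.reshape(rate.shape)
    return FieldShuffleMap(rate=out, field_id=field_id, source=ratemap)


def _histogram_field_centroids(ratemap: RateMap, rel_threshold: float = 0.10,
                               h: float = 0.8, merge_dist: float = 25.0
                               ) -> np.ndarray:
    """Field centroids for the local-order analysis: threshold at 10% of
    peak, H-maxima regional maxima (H = 0.8 Hz), then iterative merging
    of centroid pairs closer than 25 cm."""
    peak = ratemap.peak_rate
    if peak <= 0:
        return np.zeros((0, 3))
    rate = np.where(ratemap.rate >= rel_threshold * peak, ratemap.rate, 0.0)
    maxima = h_maxima(rate, h)
    lab, n = ndimage.label(maxima, structure=_STRUCT26)
    if n == 0:
        return np.zeros((0, 3))
    cents = np.array(ndimage.center_of_mass(maxima, lab, range(1, n + 1)))
    cents = ratemap.origin + (cents + 0.5) * ratemap.voxel_size
    cents = [np.asarray(c) for c in cents]
    while len(cents) > 1:
        arr = np.array(cents)
        d = np.linalg.norm(arr[:, None] - arr[None, :], axis=2)
        np.fill_diagonal(d, np.inf)
        i, j = np.unravel_index(np.argmin(d), d.shape)
        if d[i, j] >= merge_dist:
            break
        merged = 0.5 * (arr[i] + arr[j])
        cents = [c for k, c in enumerate(cents) if k not in (i, j)]
        cents.append(merged)
    return np.array(cents).reshape(-1, 3)


def _nn3_cv(cents: np.ndarray) -> float:
    """CV (sd/mean) of deduplicated 3-nearest-neighbour distances."""
    n = len(cents)
    k = min(3, n - 1)
    d = np.linalg.norm(cents[:, None] - cents[None, :], axis=2)
    np.fill_diagonal(d, np.inf)
    nn = np.sort(d, axis=1)[:, :k]
    dists = np.unique(np.round(nn.ravel(), 9))
    if len(dists) < 2:
        return 0.0
    return float(np.std(dists, ddof=1) / np.mean(dists))


def interfield_cv(traj: Trajectory, spikes: SpikeTrain,
                  voxel: float = 2.0, smooth_sd: float = 2.5,
                  n_shuffles: int = 1000, max_attempts: int = 10000,
                  field_count_tolerance: int = 3, seed: int = 0,
                  bounds=None) -> Dict:
    """Local order of the field arrangement.

    CV of the deduplicated 3-nearest-neighbour interfield distances on a
    2 cm histogram map (σ = 2.5 bins), with a field-count-matched null:
    circular spike-shift shuffles are accepted only when their field
    count is within ±``field_count_tolerance`` of the observed, up to
    ``n_shuffles`` accepted of ``max_attempts`` tries.
    """
    rng = np.random.default_rng(seed)

    def centroids_of(st):
        m = histogram_ratemap(traj, st, voxel=voxel, smooth_sd=smooth_sd,
                              bounds=bounds)
        return _histogram_field_centroids(m)

    cents = centroids_of(spikes)
    if len(cents) < 2:
        return {"cv": None, "n_fields": len(cents),
                "shuffle_cvs": np.array([]), "shuffle_mean": np.nan,
                "exceeds_shuffle": None}
    cv = _nn3_cv(cents)

    T = traj.t[-1] - traj.t[0]
    shuffle_cvs = []
    attempts = 0
    while len(shuffle_cvs) < n_shuffles and attempts < max_attempts:
        attempts += 1
        shift = 20.0 + rng.integers(0, max(int((T - 40.0) / 0.2), 1)) * 0.2
        sc = centroids_of(circular_shift(spikes, traj, shift))
        if abs(len(sc) - len(cents)) <= field_count_tolerance and len(sc) >= 2:
            shuffle_cvs.append(_nn3_cv(sc))
    shuffle_cvs = np.array(shuffle_cvs)
    mean = float(shuffle_cvs.mean()) if len(shuffle_cvs) else np.nan
    return {"cv": cv, "n_fields": len(cents), "shuffle_cvs": shuffle_cvs,
            "shuffle_mean": mean,
            "exceeds_shuffle": bool(cv > np.percentile(shuffle_cvs, 95))
            if len(shuffle_cvs) else None}


def layer_distribution_test(fieldset: FieldSet, extent_cm: float = 97.0,
                            n_layers: int = 6, n_mc: int = 1000,
                            seed: int = 0, axis: int = 2) -> Dict:
    """Are fields uniformly spread over the lattice layers?

    Field centroids are binned by layer along ``axis``; chance comes from
    ``n_mc`` draws of equally many uniform points (centred on 1/6 per
    layer for six layers); layers outside the 1st–99th percentile band
    are flagged as under/over-represented.
    """
    cents = fieldset.centroids
    nf = len(cents)
    edges = np.linspace(0.0, extent_cm, n_layers + 1)

    def props(pts):
        hcount, _ = np.histogram(pts, bins=edges)
        return hcount / max(len(pts), 1)

    obs = props(cents[:, axis]) if nf else np.zeros(n_layers)
    rng = np.random.default_rng(seed)
    mc = np.array([props(rng.uniform(0, extent_cm, size=max(nf, 1)))
                   for _ in range(n_mc)])
    lo, hi = np.percentile(mc, [1.0, 99.0], axis=0)
    return {"proportions": obs, "chance_mean": mc.mean(axis=0),
            "chance_low": lo, "chance_high": hi,
            "flagged": (obs < lo) | (obs > hi), "n_fields": nf}


def fields_per_m3(fieldset: FieldSet, dwell_map: RateMap,
                  dwell_thresh: float = 0.1) -> float:
    """Field density per m³ of practically visited space (voxels with
    average dwell above ``dwell_thresh`` seconds)."""
    if dwell_map.occupancy_unit != "seconds":
        raise ValueError("dwell_map must hold dwell seconds")
    vox_m3 = (dwell_map.voxel_size / 100.0) ** 3
    volume = float((dwell_map.occupancy > dwell_thresh).sum()) * vox_m3
    if volume <= 0:
        raise ValueError("no voxels above the dwell threshold")
    return len(fieldset) / volume


def field_size_cv(volumes_per_cell: Dict[str, np.ndarray], n: int = 100,
                  seed: int = 0) -> Dict:
    """Within-cell consistency of field volumes.

    Per cell, CV = sd/mean of its field volumes (cells with < 2 fields
    are skipped); the null pools all fields across cells, shuffles cell
    identities and recomputes the per-cell CVs ``n`` times.
    """
    rng = np.random.default_rng(seed)
    cells = {c: np.asarray(v, dtype=float) for c, v in volumes_per_cell.items()
             if len(v) >= 2}
    if not cells:
        return {"cv": {}, "shuffled_cvs": np.zeros((n, 0)), "cells": []}

    def cv(v):
        return float(np.std(v, ddof=1) / np.mean(v))

    observed = {c: cv(v) for c, v in cells.items()}
    pool = np.concatenate(list(cells.values()))
    sizes = [len(v) for v in cells.values()]
    shuffled = np.empty((n, len(cells)))
    for i in range(n):
        perm = rng.permutation(pool)
        start = 0
        for j, s in enumerate(sizes):
            shuffled[i, j] = cv(perm[start:start + s])
            start += s
    return {"cv": observed, "shuffled_cvs": shuffled,
            "cells": list(cells.keys())}
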