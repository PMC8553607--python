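"""Planar-symmetry analysis of 3D autocorrelograms.

Close-packed field arrangements betray themselves through the gridness of
oblique central slices: an axis-aligned FCC autocorrelation shows a
hexagonal horizontal slice, three more hexagonal planes at ~72° pitch
spaced 120° apart in azimuth, and three square planes at ~50° pitch
offset 60° in azimuth from the hexagonal ones; HCP shares the hexagonal
planes but its square planes sit at the *same* azimuths; columnar
arrangements score hexagonally at shallow pitches only.  Scoring every
plane through the autocorrelation centre (65 pitch × 65 azimuth = 4,225
planes) and contrasting medians over the relevant (pitch, azimuth) rings
yields the structure scores χ_CP, χ_FCC, χ_HCP and χ_COL that separate
FCC, HCP, columnar and random field configurations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .autocorr import autocorrelation, central_crop
from .containers import Autocorr3D, RateMap, ScoreSphere
from .gridscore import score_slices

__all__ = [
    "sample_planes",
    "score_rings",
    "best_plane_correct",
    "interpolate_sphere",
    "structure_scores",
    "classify_configuration",
    "best_plane_slice_hgs",
    "planar_analysis",
    "ring_peak_azimuths",
    "StructureScores",
    "HEX_PITCH_DEG",
    "SQUARE_PITCH_DEG",
]

#: nominal pitch of the oblique hexagonal planes of a close-packed
#: arrangement (the operational value; ideal FCC geometry gives
#: arccos(1/3) ≈ 70.5°)
HEX_PITCH_DEG = 72.0
#: nominal pitch of the square-arrangement planes (operational value;
#: ideal geometry gives ≈ 54.7°)
SQUARE_PITCH_DEG = 50.0


def _plane_basis(pitch_rad: float, azim_rad: float):
    """Normal and in-plane orthonormal basis of the central plane tilted
    by ``pitch`` from horizontal toward compass direction ``azimuth``."""
    st, ct = np.sin(pitch_rad), np.cos(pitch_rad)
    sp, cp = np.sin(azim_rad), np.cos(azim_rad)
    n = np.array([st * cp, st * sp, ct])
    u = np.array([-sp, cp, 0.0])
    v = np.cross(n, u)
    return n, u, v


def sample_planes(ac: Autocorr3D, n_pitch: int = 65, n_azimuth: int = 65,
                  slice_half_width: Optional[int] = None) -> ScoreSphere:
    """Score the central oblique slice at every (pitch, azimuth).

    Pitch spans [0°, 90°] and azimuth [0°, 360°) — with pitch measured
    from horizontal each oblique plane appears once.  Slices are square,
    sampled at the voxel pitch by trilinear interpolation (NaN outside
    the volume), then scored with the HGS/SGS machinery.  The default
    slice half-width is min(28, what fits): with the package's 41³ rate
    volumes the lattice period is ~17 voxels, so 28 comfortably covers
    the six-peak hexagonal annulus and the diagonal peaks of square
    slices while keeping the 4,225-plane sweep fast.
    """
    if min(ac.r.shape) < 15:
        raise ValueError("autocorrelation too small to slice (< 15 voxels/side)")
    pitch = np.linspace(0.0, 90.0, n_pitch)
    azim = np.arange(n_azimuth) * 360.0 / n_azimuth
    hgs_m, sgs_m = _score_plane_grid(ac.r, pitch, azim, slice_half_width)
    return ScoreSphere(pitch_deg=pitch, azimuth_deg=azim, hgs=hgs_m, sgs=sgs_m)


def _score_plane_grid(vol: np.ndarray, pitch_deg: np.ndarray,
                      azim_deg: np.ndarray,
                      slice_half_width: Optional[int] = None):
    """Extract and score the central oblique slice for every combination
    of the given pitch and azimuth angles; returns (hgs, sgs) maps of
    shape (n_pitch, n_azimuth)."""
    n_pitch, n_azimuth = len(pitch_deg), len(azim_deg)
    if slice_half_width is None:
        slice_half_width = min(28, (min(vol.shape) - 1) // 2)
    half = int(slice_half_width)
    s = np.arange(-half, half + 1, dtype=np.float32)
    c = (np.asarray(vol.shape, dtype=np.float32) - 1) / 2.0

    th = np.radians(pitch_deg).astype(np.float32)[:, None]
    ph = np.radians(azim_deg).astype(np.float32)[None, :]
    n = np.empty((n_pitch, n_azimuth, 3), dtype=np.float32)
    n[..., 0] = np.sin(th) * np.cos(ph)
    n[..., 1] = np.sin(th) * np.sin(ph)
    n[..., 2] = np.cos(th) * np.ones_like(ph)
    u = np.empty_like(n)
    u[..., 0] = -np.sin(ph) * np.ones_like(th)
    u[..., 1] = np.cos(ph) * np.ones_like(th)
    u[..., 2] = 0.0
    v = np.cross(n, u)
    # (P, A, h, h, 3) sample points in voxel coordinates
    pts = (c[None, None, None, None, :] +
           s[None, None, :, None, None] * u[:, :, None, None, :] +
           s[None, None, None, :, None] * v[:, :, None, None, :])
    flat = pts.reshape(-1, 3).T
    vals = ndimage.map_coordinates(
        np.nan_to_num(vol, nan=0.0).astype(np.float32), flat,
        order=1, mode="constant", cval=np.nan)
    if np.isnan(vol).any():
        # undefined lags must not leak zeros into the slices
        ok = ndimage.map_coordinates(np.isfinite(vol).astype(np.float32), flat,
                                     order=1, mode="constant", cval=0.0)
        vals[ok < 0.999] = np.nan
    stack = vals.reshape(n_pitch * n_azimuth, len(s), len(s))

    hgs_v, sgs_v, _ = score_slices(stack)
    return (hgs_v.reshape(n_pitch, n_azimuth),
            sgs_v.reshape(n_pitch, n_azimuth))


def score_rings(ac: Autocorr3D, pitch_deg: Sequence[float],
                n_azimuth: int = 128) -> Dict[float, Dict[str, np.ndarray]]:
    """HGS/SGS around full azimuth rings at the given pitches (used to
    read the χ-score rings directly off a best-plane-corrected volume)."""
    azim = np.arange(n_azimuth) * 360.0 / n_azimuth
    hgs_m, sgs_m = _score_plane_grid(ac.r, np.asarray(pitch_deg, float), azim)
    return {float(p): {"azimuth_deg": azim, "hgs": hgs_m[i], "sgs": sgs_m[i]}
            for i, p in enumerate(pitch_deg)}


def _nn_lookup(src_dirs: np.ndarray, values: np.ndarray,
               query_dirs: np.ndarray) -> np.ndarray:
    """Spherical nearest-neighbour lookup of *defined* scores.

    The neighbour minimises the great-circle angle (equivalently the
    chord) between unoriented plane normals; NaN-scored source planes are
    excluded, so every query inherits the nearest scorable plane's value.
    """
    flat = values.ravel()
    ok = np.isfinite(flat)
    if not ok.any():
        return np.full(len(query_dirs), np.nan)
    dirs = src_dirs[ok]
    tree = cKDTree(np.vstack([dirs, -dirs]))
    _, idx = tree.query(query_dirs)
    return flat[ok][np.mod(idx, ok.sum())]


def _regrid_sphere(sphere: ScoreSphere, R: np.ndarray) -> ScoreSphere:
    """Re-express a score sphere in a rotated frame (R maps old directions
    to new) by spherical nearest-neighbour lookup."""
    old_dirs = sphere.plane_normals().reshape(-1, 3)
    new = ScoreSphere(pitch_deg=sphere.pitch_deg, azimuth_deg=sphere.azimuth_deg,
                      hgs=np.empty_like(sphere.hgs), sgs=np.empty_like(sphere.sgs))
    query = new.plane_normals().reshape(-1, 3) @ R   # R^{-1} m = m @ R
    new.hgs = _nn_lookup(old_dirs, sphere.hgs, query).reshape(sphere.hgs.shape)
    new.sgs = _nn_lookup(old_dirs, sphere.sgs, query).reshape(sphere.sgs.shape)
    return new


def _rotation_to_z(n: np.ndarray) -> np.ndarray:
    """Rotation matrix taking unit vector n to +z."""
    z = np.array([0.0, 0.0, 1.0])
    cosang = float(np.clip(n @ z, -1, 1))
    if cosang > 1 - 1e-12:
        return np.eye(3)
    if cosang < -1 + 1e-12:
        return np.diag([1.0, -1.0, -1.0])
    axis = np.cross(n, z)
    axis /= np.linalg.norm(axis)
    ang = np.arccos(cosang)
    K = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(ang) * K + (1 - np.cos(ang)) * (K @ K)


def _refine_best_plane(ac: Autocorr3D, pitch0: float, azim0: float,
                       half_range: float = 3.0, step: float = 0.75
                       ) -> Tuple[float, float]:
    """Sharpen the best-plane angles with a fine local sweep around the
    native-grid maximum (the native azimuth step is ~5.5°, coarser than
    the square-plane SGS peaks read off the corrected frame)."""
    dp = np.arange(-half_range, half_range + step / 2, step)
    pitches = np.clip(pitch0 + dp, 0.0, 90.0)
    azims = (azim0 + dp) % 360.0
    hgs_m, _ = _score_plane_grid(ac.r, pitches, azims)
    if not np.isfinite(hgs_m).any():
        return pitch0, azim0
    i, j = np.unravel_index(np.nanargmax(hgs_m), hgs_m.shape)
    return float(pitches[i]), float(azims[j])


def best_plane_correct(ac: Autocorr3D, sphere: ScoreSphere,
                       rotate_volume: bool = True, refine: bool = False
                       ) -> Tuple[Optional[Autocorr3D], ScoreSphere]:
    """Rotate the frame so the maximum-HGS plane becomes horizontal.

    Returns the rotated autocorrelation (trilinear, NaN-padded; None when
    ``rotate_volume`` is False, which callers needing only the
    re-expressed sphere may use) and the sphere re-expressed in the new
    frame.  Ties in HGS break toward the lowest pitch; ``refine`` adds a
    fine local sweep around the native-grid best plane.
    """
    bp, ba = sphere.best_plane()
    if refine:
        bp, ba = _refine_best_plane(ac, bp, ba)
    n, _, _ = _plane_basis(np.radians(bp), np.radians(ba))
    R = _rotation_to_z(n)
    new_sphere = _regrid_sphere(sphere, R)

    rotated = None
    if rotate_volume:
        c = (np.asarray(ac.r.shape) - 1) / 2.0
        filled = np.nan_to_num(ac.r, nan=0.0)
        valid = np.isfinite(ac.r).astype(float)
        # cubic interpolation keeps the narrow correlation peaks the
        # ring reads depend on; validity transported separately
        out = ndimage.affine_transform(filled, R.T, offset=c - R.T @ c,
                                       order=3, mode="constant", cval=0.0)
        vout = ndimage.affine_transform(valid, R.T, offset=c - R.T @ c,
                                        order=1, mode="constant", cval=0.0)
        out[vout < 0.5] = np.nan
        nout = ndimage.affine_transform(ac.n_overlap.astype(float), R.T,
                                        offset=c - R.T @ c, order=1,
                                        mode="constant", cval=0.0)
        rotated = Autocorr3D(r=out, n_overlap=np.round(nout).astype(int),
                             voxel_size=ac.voxel_size)
    return rotated, new_sphere


def interpolate_sphere(sphere: ScoreSphere, n: int = 128) -> ScoreSphere:
    """Spherical nearest-neighbour interpolation up to an n × n grid.

    The neighbour is the native direction with the smallest great-circle
    angle (equivalently smallest chord), so native grid points keep their
    values exactly.
    """
    pitch = np.linspace(0.0, 90.0, n)
    azim = np.arange(n) * 360.0 / n
    out = ScoreSphere(pitch_deg=pitch, azimuth_deg=azim,
                      hgs=np.empty((n, n)), sgs=np.empty((n, n)))
    old_dirs = sphere.plane_normals().reshape(-1, 3)
    query = out.plane_normals().reshape(-1, 3)
    out.hgs = _nn_lookup(old_dirs, sphere.hgs, query).reshape(n, n)
    out.sgs = _nn_lookup(old_dirs, sphere.sgs, query).reshape(n, n)
    return out


@dataclass
class StructureScores:
    """χ structure scores of one (best-plane-corrected) score sphere."""

    chi_cp: float
    chi_fcc: float
    chi_hcp: float
    chi_col: float
    hex_azimuths: np.ndarray
    components: Dict[str, float]

    def as_dict(self) -> Dict[str, float]:
        return {"CP": self.chi_cp, "FCC": self.chi_fcc,
                "HCP": self.chi_hcp, "COL": self.chi_col}


def _ring_index(pitch_grid: np.ndarray, nominal: float) -> int:
    return int(np.argmin(np.abs(pitch_grid - nominal)))


def _fill_ring(vals: np.ndarray, fallback: np.ndarray) -> np.ndarray:
    """Fill NaNs circularly from the nearest finite azimuth; when the
    whole ring is NaN, return ``fallback`` (resampled to its length)."""
    vals = np.asarray(vals, dtype=float)
    ok = np.isfinite(vals)
    if not ok.any():
        if len(fallback) == len(vals):
            return np.asarray(fallback, dtype=float)
        src = np.linspace(0, 1, len(fallback), endpoint=False)
        dst = np.linspace(0, 1, len(vals), endpoint=False)
        return np.interp(dst, src, fallback, period=1.0)
    if ok.all():
        return vals
    A = len(vals)
    idx = np.flatnonzero(ok)
    out = vals.copy()
    for i in np.flatnonzero(~ok):
        d = np.minimum(np.abs(idx - i), A - np.abs(idx - i))
        out[i] = vals[idx[int(np.argmin(d))]]
    return out


def structure_scores(sphere: ScoreSphere, interp_n: int = 128,
                     col_band_deg: float = 60.0,
                     rings: Optional[Dict] = None) -> StructureScores:
    """Compute χ_CP, χ_FCC, χ_HCP and χ_COL.

    The sphere must already be best-plane corrected; it is interpolated
    to ``interp_n`` × ``interp_n`` (nearest-neighbour on the sphere)
    before any median is taken.  Unscorable planes contribute nothing to
    the medians.

    χ_CP  = median({HGS at 72° pitch} ∪ {SGS at 50° pitch})
    hex azimuths = the 120°-spaced azimuth triple at 72° pitch with the
                   largest summed HGS
    χ_FCC = median SGS(hex ± 60°, 50°) − median SGS(hex, 50°)
    χ_HCP = median SGS(hex, 50°) − median SGS(hex, 72°)
    χ_COL = median HGS(pitch ≤ 60°) − median HGS(pitch > 60°)

    When ``rings`` (from :func:`score_rings` on a best-plane-rotated
    volume) is given, the 72°/50° pitch rings are read from those
    natively scored planes instead of the regridded sphere — the square-
    plane SGS peaks are only a few degrees wide, so ring values scored
    directly in the corrected frame are markedly more accurate.  χ_COL,
    a broad-band median, always comes from the sphere.
    """
    if len(sphere.pitch_deg) != interp_n:
        sphere = interpolate_sphere(sphere, interp_n)
    pitch, azim = sphere.pitch_deg, sphere.azimuth_deg
    i72 = _ring_index(pitch, HEX_PITCH_DEG)
    i50 = _ring_index(pitch, SQUARE_PITCH_DEG)
    hgs72 = sphere.hgs[i72]
    sgs50 = sphere.sgs[i50]
    sgs72 = sphere.sgs[i72]
    if rings is not None:
        hex_ring = rings[HEX_PITCH_DEG]
        sq_ring = rings[SQUARE_PITCH_DEG]
        azim = hex_ring["azimuth_deg"]
        # unscorable azimuths inherit the nearest scorable plane on the
        # same ring; a fully unscorable ring falls back to the sphere
        hgs72 = _fill_ring(hex_ring["hgs"], hgs72)
        sgs72 = _fill_ring(hex_ring["sgs"], sgs72)
        sgs50 = _fill_ring(sq_ring["sgs"], sgs50)
    A = len(azim)

    def med(v):
        v = v[np.isfinite(v)]
        return float(np.median(v)) if v.size else np.nan

    chi_cp = med(np.concatenate([hgs72, sgs50]))

    o120 = int(round(A * 120.0 / 360.0))
    o240 = int(round(A * 240.0 / 360.0))
    totals = np.full(A, -np.inf)
    for a in range(A):
        idx = np.array([a, (a + o120) % A, (a + o240) % A])
        vals = hgs72[idx]
        if np.isfinite(vals).any():
            totals[a] = np.nansum(vals)
    a0 = int(np.argmax(totals))
    hex_idx = np.array([a0, (a0 + o120) % A, (a0 + o240) % A])

    o60 = int(round(A * 60.0 / 360.0))
    off_idx = np.unique(np.concatenate([(hex_idx + o60) % A,
                                        (hex_idx - o60) % A]))
    beta_fcc = med(sgs50[hex_idx])
    alpha_fcc = med(sgs50[off_idx])
    chi_fcc = alpha_fcc - beta_fcc

    alpha_hcp = med(sgs50[hex_idx])
    beta_hcp = med(sgs72[hex_idx])
    chi_hcp = alpha_hcp - beta_hcp

    near = pitch <= col_band_deg
    alpha_col = med(sphere.hgs[near].ravel())
    beta_col = med(sphere.hgs[~near].ravel())
    chi_col = alpha_col - beta_col

    comps = {"alpha_fcc": alpha_fcc, "beta_fcc": beta_fcc,
             "alpha_hcp": alpha_hcp, "beta_hcp": beta_hcp,
             "alpha_col": alpha_col, "beta_col": beta_col}
    return StructureScores(chi_cp=chi_cp, chi_fcc=chi_fcc, chi_hcp=chi_hcp,
                           chi_col=chi_col, hex_azimuths=azim[hex_idx],
                           components=comps)


def classify_configuration(scores: StructureScores,
                           reference_sims: Optional[Dict[str, np.ndarray]] = None,
                           method: str = "argmax",
                           floor: float = 0.6) -> str:
    """Label a cell's field configuration.

    ``argmax``: the structured label (FCC/HCP/COL) with the largest χ, or
    RND when all fall below ``floor``.  The default floor sits midway
    between the score ranges of the generator's structured reference
    arrangements (argmax χ ≳ 1) and of uniform-random ones (spurious χ
    stays ≲ 0.5 even when few planes are scorable).  ``hull``: membership
    in the convex hull of each reference simulation cloud in
    (χ_FCC, χ_HCP, χ_COL) space; 'uncategorized' when in none or several.
    """
    triple = np.array([scores.chi_fcc, scores.chi_hcp, scores.chi_col])
    if method == "argmax":
        labels = np.array(["FCC", "HCP", "COL"])
        if not np.isfinite(triple).any() or np.nanmax(triple) < floor:
            return "RND"
        return str(labels[int(np.nanargmax(triple))])
    if method == "hull":
        if not reference_sims:
            raise ValueError("hull method needs reference simulation clouds")
        from scipy.spatial import Delaunay
        hits = [lbl for lbl, cloud in reference_sims.items()
                if Delaunay(np.asarray(cloud)).find_simplex(triple) >= 0]
        return hits[0] if len(hits) == 1 else "uncategorized"
    raise ValueError(f"unknown method {method!r}")


def ring_peak_azimuths(sphere: ScoreSphere, pitch_deg: float,
                       score: str = "hgs", n_peaks: int = 3,
                       min_separation: float = 30.0) -> np.ndarray:
    """Azimuths of the strongest circular local maxima of HGS or SGS on
    the sampled pitch ring nearest ``pitch_deg`` (used to locate the
    oblique hexagonal and square planes of close-packed arrangements)."""
    i = _ring_index(sphere.pitch_deg, pitch_deg)
    ring = np.nan_to_num(getattr(sphere, score)[i], nan=-np.inf)
    A = len(ring)
    is_max = (ring >= np.roll(ring, 1)) & (ring >= np.roll(ring, -1)) & \
        np.isfinite(ring)
    cand = np.flatnonzero(is_max)
    cand = cand[np.argsort(ring[cand])[::-1]]
    chosen = []
    for a in cand:
        az = sphere.azimuth_deg[a]
        sep = [min(abs(az - b), 360 - abs(az - b)) for b in chosen]
        if all(s2 >= min_separation for s2 in sep):
            chosen.append(az)
        if len(chosen) == n_peaks:
            break
    return np.sort(np.array(chosen))


def best_plane_slice_hgs(ratemap: RateMap, n_pitch: int = 65,
                         n_azimuth: int = 65) -> float:
    """Maximum HGS over every plane sliced through a volumetric map's
    autocorrelation — a hexagonal pattern at *any* orientation scores
    high; compared against a spike-shuffle null downstream."""
    sphere = sample_planes(autocorrelation(ratemap), n_pitch, n_azimuth)
    if not np.isfinite(sphere.hgs).any():
        return np.nan
    return float(np.nanmax(sphere.hgs))


def planar_analysis(ratemap: RateMap, n_pitch: int = 65, n_azimuth: int = 65,
                    anisotropy: bool = False,
                    min_scorable_fraction: float = 0.05
                    ) -> Tuple[ScoreSphere, StructureScores]:
    """Full pipeline: autocorrelation → plane sweep → best-plane
    correction → χ structure scores.

    When the undefined (low-overlap) lags are confined to the extreme
    corners, the volume is cropped to its NaN-free central cube first —
    the slice sweep then needs no per-sample validity interpolation.

    χ scores are reported only when at least ``min_scorable_fraction`` of
    the sampled planes are scorable: medians over a handful of isolated
    planes carry no information about planar symmetry (uniform-random
    arrangements score ≲ 2% of planes, structured ones ≳ 70%).
    """
    from .autocorr import anisotropy_correct, nan_free_half_width
    ac = autocorrelation(ratemap)
    if anisotropy:
        ac = anisotropy_correct(ac)
    h = nan_free_half_width(ac)
    if h >= 15:
        ac = central_crop(ac, h)
    sphere = sample_planes(ac, n_pitch, n_azimuth)
    if np.isfinite(sphere.hgs).mean() < min_scorable_fraction:
        # no pervasive planar structure: no best plane, all chi undefined
        return sphere, StructureScores(
            chi_cp=np.nan, chi_fcc=np.nan, chi_hcp=np.nan, chi_col=np.nan,
            hex_azimuths=np.full(3, np.nan),
            components={"reason": "fewer than "
                        f"{min_scorable_fraction:.0%} of planes scorable"})
    rotated, corrected = best_plane_correct(ac, sphere, rotate_volume=True,
                                            refine=True)
    rings = score_rings(rotated, [HEX_PITCH_DEG, SQUARE_PITCH_DEG])
    return corrected, structure_scores(corrected, rings=rings)
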