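"""Synthetic recordings with the statistical structure the analysis assumes.

Three generators emulate lattice-maze grid-cell recordings end to end:

* :func:`make_arrangement` / :func:`arrangement_ratemap` build idealised
  3D firing-rate volumes whose fields form hexagonal-close-packed (HCP),
  face-centered-cubic (FCC), columnar (COL) or uniformly random (RND)
  arrangements.  Hexagon side ``S`` is the in-plane nearest-neighbour
  distance; close-packed layers stack along z at (√6/3)·S ≈ 0.816·S.
* :func:`simulate_trajectory` produces seeded random-walk paths through a
  climbing-lattice, open-arena or free-volume environment, with a
  horizontal-movement bias and a floor-dwell bias mimicking real rat
  coverage anisotropy.
* :func:`generate_spikes` draws an inhomogeneous Poisson spike train from
  any rate map along a trajectory.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .containers import RateMap, SpikeTrain, Trajectory

__all__ = [
    "ArrangementSpec",
    "PointLattice",
    "TrajectorySpec",
    "make_arrangement",
    "arrangement_ratemap",
    "simulate_trajectory",
    "generate_spikes",
    "reference_arrangement",
    "subseed",
    "LAYER_STEP_FACTOR",
]

#: z-separation of successive close-packed layers in units of S: √6/3 ≈ 0.816
LAYER_STEP_FACTOR = np.sqrt(6.0) / 3.0

#: number of stacked point copies per S used to approximate continuous columns
_COL_SUBDIV = 25

#: default bounding box is the 0.97 m lattice cube scaled to the field
#: spacing (0.97 m corresponds to S = 400 mm), so arrangements of any S
#: contain the same number of spatial periods as the recorded maze did at
#: the modal spacing.
_EXTENT_PER_S = 970.0 / 400.0


def subseed(master: int, *keys) -> int:
    """Derive a stable sub-seed (< 2**31) from a master seed and labels."""
    h = hashlib.sha256(repr((int(master),) + tuple(keys)).encode()).digest()
    return int.from_bytes(h[:4], "little") % (2**31)


@dataclass
class ArrangementSpec:
    """Parameters of a simulated field arrangement.

    S is the hexagon side length in mm (reference simulations draw it
    uniformly from [200, 600] mm per cell); sigma is the Gaussian field
    width in voxels (default 2); rotation optionally turns the volume
    by ``angle_deg`` about a unit ``axis``.
    """

    kind: str                       # 'HCP' | 'FCC' | 'COL' | 'RND'
    S: float = 400.0                # mm
    sigma: float = 2.0              # voxels
    rotation: Optional[Tuple[np.ndarray, float]] = None  # (axis, angle_deg)
    extent: Optional[np.ndarray] = None                  # mm, (3,)
    seed: int = 0

    def __post_init__(self):
        self.kind = self.kind.upper()
        if self.kind not in ("HCP", "FCC", "COL", "RND"):
            raise ValueError(f"unknown arrangement kind {self.kind!r}")
        if self.S <= 0 or self.sigma <= 0:
            raise ValueError("S and sigma must be positive")
        if self.extent is None:
            self.extent = np.full(3, _EXTENT_PER_S * self.S)
        self.extent = np.asarray(self.extent, dtype=float)
        if np.any(self.extent <= 0):
            raise ValueError("extent must be positive in all dimensions")
        if self.rotation is not None:
            axis, ang = self.rotation
            axis = np.asarray(axis, dtype=float)
            axis = axis / np.linalg.norm(axis)
            self.rotation = (axis, float(ang))


@dataclass
class PointLattice:
    """Field-centre coordinates (mm) with their stacking-layer index."""

    points: np.ndarray
    layer_index: np.ndarray
    kind: str = ""

    @property
    def n(self) -> int:
        return len(self.points)


def _hex_layer(S: float, extent: np.ndarray, y_offset: float = 0.0) -> np.ndarray:
    """One hexagonal layer: x-spacing S, row spacing √3·S/2, alternate rows
    offset by S/2 in x; overfilled then cropped to [0, extent]."""
    row_dy = np.sqrt(3.0) * 0.5 * S
    # overfill generously: offsets only ever shift by ~one period
    jmax = int(np.ceil((extent[1] + 2 * S) / row_dy)) + 2
    imax = int(np.ceil((extent[0] + 2 * S) / S)) + 2
    pts = []
    for j in range(-jmax, jmax + 1):
        y = j * row_dy + y_offset
        if y < -1e-9 or y > extent[1] + 1e-9:
            continue
        x0 = (S / 2.0) if (j % 2) else 0.0
        for i in range(-imax, imax + 1):
            x = i * S + x0
            if -1e-9 <= x <= extent[0] + 1e-9:
                pts.append((x, y))
    return np.array(pts, dtype=float).reshape(-1, 2)


def make_arrangement(spec: ArrangementSpec) -> PointLattice:
    """Generate field-centre points for the requested arrangement.

    HCP stacks hexagonal layers at z-steps of (√6/3)·S with every second
    layer offset in y by √3·S/3 (ABA stacking); FCC cycles three lateral
    offsets 0, +√3·S/3, −√3·S/3 (ABC stacking); COL repeats one layer in
    fine z-steps to approximate continuous columns; RND draws as many
    uniform points as the matching HCP arrangement contains.
    """
    S, extent = spec.S, spec.extent
    dz = LAYER_STEP_FACTOR * S
    y_unit = np.sqrt(3.0) * S / 3.0

    if extent[0] < S or extent[1] < np.sqrt(3.0) * 0.5 * S:
        raise ValueError("extent too small to contain one full hexagonal layer")

    def stack(step: float, offset_of):
        pts, layers = [], []
        k = 0
        while k * step <= extent[2] + 1e-9:
            layer = _hex_layer(S, extent, y_offset=offset_of(k))
            if layer.size:
                pts.append(np.column_stack([layer, np.full(len(layer), k * step)]))
                layers.append(np.full(len(layer), k, dtype=int))
            k += 1
        return np.vstack(pts), np.concatenate(layers)

    if spec.kind == "HCP":
        points, layer = stack(dz, lambda k: (k % 2) * y_unit)
    elif spec.kind == "FCC":
        offs = {0: 0.0, 1: y_unit, 2: -y_unit}
        points, layer = stack(dz, lambda k: offs[k % 3])
    elif spec.kind == "COL":
        points, layer = stack(S / _COL_SUBDIV, lambda k: 0.0)
    else:  # RND: match the HCP point count inside the same cuboid
        hcp = make_arrangement(ArrangementSpec("HCP", S=S, sigma=spec.sigma,
                                               extent=extent, seed=spec.seed))
        rng = np.random.default_rng(spec.seed)
        points = rng.uniform(0.0, 1.0, size=(hcp.n, 3)) * extent
        layer = np.zeros(hcp.n, dtype=int)
    return PointLattice(points=points, layer_index=layer, kind=spec.kind)


def arrangement_ratemap(lattice: PointLattice, spec: ArrangementSpec,
                        voxel_mm: Optional[float] = None,
                        n_voxels: int = 41) -> RateMap:
    """Rate volume g(x) = exp(−0.5 (x/σ)²) of the distance to the nearest
    field point, optionally rotated about a 3D axis.

    Rotation is applied to the field points themselves (regenerated on an
    enlarged box, turned about the volume centre, cropped), so the
    rotated volume is sampled exactly rather than resampled — the narrow
    autocorrelation peaks the planar-symmetry analysis reads are
    preserved with no interpolation loss.  ``voxel_mm`` defaults to
    extent/``n_voxels`` so the default volume is 41³ regardless of S;
    rates are normalised with peak 1.
    """
    if lattice.n == 0:
        raise ValueError("empty lattice")
    extent = spec.extent
    if voxel_mm is None:
        voxel_mm = float(extent[0]) / n_voxels
    shape = tuple(int(round(e / voxel_mm)) for e in extent)

    points = lattice.points
    if spec.rotation is not None:
        axis, ang = spec.rotation
        R = Rotation.from_rotvec(np.radians(ang) * axis).as_matrix()
        big = ArrangementSpec(spec.kind, S=spec.S, sigma=spec.sigma,
                              extent=spec.extent * 2.0, seed=spec.seed)
        pts = make_arrangement(big).points
        c_big = big.extent / 2.0
        c = extent / 2.0
        points = (pts - c_big) @ R.T + c
        keep = np.all((points >= -1e-9) & (points <= extent + 1e-9), axis=1)
        if keep.any():
            points = points[keep]

    axes = [(np.arange(s) + 0.5) * voxel_mm for s in shape]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    coords = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    dist, _ = cKDTree(points).query(coords, workers=-1)
    sigma_mm = spec.sigma * voxel_mm
    vol = np.exp(-0.5 * (dist / sigma_mm) ** 2).reshape(shape)

    ones = np.ones(shape)
    return RateMap(rate=vol, occupancy=ones, spikes=np.zeros(shape),
                   voxel_size=voxel_mm / 10.0, origin=np.zeros(3),
                   visited=ones.astype(bool), occupancy_unit="samples")


@dataclass
class TrajectorySpec:
    """Random-walk parameters.

    ``environment`` is one of 'lattice' (axis-aligned walk on climbing-bar
    edges), 'arena' (planar walk in the 1.2 m open field) or 'volume'
    (free 3D walk, useful for dense-coverage tests).  ``horizontal_bias``
    multiplies the probability of horizontal steps and ``floor_bias`` that
    of steps onto the bottom lattice layer (both ≥ 1).
    """

    duration: float = 600.0        # s
    sample_rate: float = 25.0      # Hz
    environment: str = "lattice"
    horizontal_bias: float = 3.0
    floor_bias: float = 2.0
    mean_speed: float = 10.0       # cm/s
    size_cm: Optional[float] = None
    n_cells_per_side: int = 6
    seed: int = 0

    def __post_init__(self):
        if self.duration <= 0 or self.sample_rate <= 0:
            raise ValueError("duration and sample_rate must be positive")
        if self.horizontal_bias < 1 or self.floor_bias < 1:
            raise ValueError("biases must be >= 1")
        if self.environment not in ("lattice", "arena", "volume"):
            raise ValueError(f"unknown environment {self.environment!r}")
        if self.size_cm is None:
            self.size_cm = 120.0 if self.environment == "arena" else 97.0


def _lattice_walk(spec: TrajectorySpec, rng) -> np.ndarray:
    """Continuous walk along the axis-aligned bars of the climbing lattice."""
    n_nodes = spec.n_cells_per_side + 1
    pitch = spec.size_cm / spec.n_cells_per_side
    dt = 1.0 / spec.sample_rate
    n = int(round(spec.duration * spec.sample_rate))
    steps = np.array([[1, 0, 0], [-1, 0, 0], [0, 1, 0],
                      [0, -1, 0], [0, 0, 1], [0, 0, -1]])

    def next_node(node, prev):
        cand = node + steps
        w = np.where(steps[:, 2] == 0, spec.horizontal_bias, 1.0)
        w = w * np.where(cand[:, 2] == 0, spec.floor_bias, 1.0)
        w[~np.all((cand >= 0) & (cand < n_nodes), axis=1)] = 0.0
        if prev is not None:            # avoid immediate backtracking
            back = np.all(cand == prev, axis=1)
            if w[~back].sum() > 0:
                w[back] = 0.0
        return cand[rng.choice(len(steps), p=w / w.sum())]

    node = np.array([n_nodes // 2, n_nodes // 2, 0])
    prev = None
    target = next_node(node, prev)
    dist = 0.0                           # cm travelled along the current edge
    speed = spec.mean_speed
    pos = np.empty((n, 3))
    for i in range(n):
        dist += speed * dt
        while dist >= pitch:
            dist -= pitch
            prev, node = node, target
            target = next_node(node, prev)
            speed = max(spec.mean_speed / 3.0,
                        rng.normal(spec.mean_speed, 0.2 * spec.mean_speed))
        pos[i] = (node + (dist / pitch) * (target - node)) * pitch
    return pos


def _bounded_walk(spec: TrajectorySpec, rng, planar: bool) -> np.ndarray:
    dt = 1.0 / spec.sample_rate
    n = int(round(spec.duration * spec.sample_rate))
    hi = spec.size_cm
    dim = 2 if planar else 3
    p = rng.uniform(0.2 * hi, 0.8 * hi, size=3)
    if planar:
        p[2] = 0.0
    d = rng.normal(size=dim)
    d /= np.linalg.norm(d)
    pos = np.empty((n, 3))
    for i in range(n):
        pos[i] = p
        speed = max(spec.mean_speed / 3.0,
                    rng.normal(spec.mean_speed, 0.2 * spec.mean_speed))
        d = d + rng.normal(scale=0.35, size=dim)
        d /= np.linalg.norm(d)
        step = d * speed * dt
        for k in range(dim):
            nxt = p[k] + step[k]
            if nxt < 0 or nxt > hi:      # reflect at the walls
                d[k] = -d[k]
                nxt = np.clip(2 * np.clip(nxt, 0, hi) - nxt, 0, hi)
            p[k] = nxt
    return pos


def simulate_trajectory(spec: TrajectorySpec) -> Trajectory:
    """Seeded random-walk trajectory for the requested environment."""
    rng = np.random.default_rng(spec.seed)
    if spec.environment == "lattice":
        pos = _lattice_walk(spec, rng)
    else:
        pos = _bounded_walk(spec, rng, planar=(spec.environment == "arena"))
    t = np.arange(len(pos)) / spec.sample_rate
    return Trajectory(t=t, pos=pos)


def reference_arrangement(kind: str, seed: int, rotate_deg: float = 30.0,
                          s_range: Tuple[float, float] = (200.0, 600.0)):
    """One study-conditions reference simulation: hexagon side S drawn
    uniformly from [200, 600] mm, field width sigma = 2 voxels, and the
    arrangement turned ``rotate_deg`` about a random 3D axis.  Returns
    (ratemap, spec)."""
    rng = np.random.default_rng(subseed(seed, "reference", kind))
    S = float(rng.uniform(*s_range))
    rotation = None
    if rotate_deg:
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        rotation = (axis, rotate_deg)
    spec = ArrangementSpec(kind, S=S, sigma=2.0, rotation=rotation, seed=seed)
    return arrangement_ratemap(make_arrangement(spec), spec), spec


def generate_spikes(ratemap: RateMap, traj: Trajectory, gain_hz: float = 1.0,
                    seed: int = 0, cell_id: str = "sim") -> SpikeTrain:
    """Inhomogeneous Poisson spikes: the expected count in each tracking
    interval is gain_hz · (map value at the sample position) · dt."""
    rng = np.random.default_rng(seed)
    dt = np.r_[np.diff(traj.t), 1.0 / traj.sample_rate]
    idx = np.floor((traj.pos - ratemap.origin) / ratemap.voxel_size).astype(int)
    idx = np.clip(idx, 0, np.asarray(ratemap.shape) - 1)
    lam = gain_hz * ratemap.rate[tuple(idx[:, k] for k in range(3))] * dt
    counts = rng.poisson(np.clip(lam, 0, None))
    times = np.repeat(traj.t, counts) + rng.uniform(0, 1, counts.sum()) * np.repeat(dt, counts)
    return SpikeTrain(times=np.sort(times), cell_id=cell_id)
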