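"""Reading and writing sessions, rate maps and result tables.

Trajectories and spike trains travel as delimited text (columns
``t,x,y,z`` / ``t``) or together in one HDF5 container; rate maps and
autocorrelations are stored in HDF5 with voxel size, origin and axis
order recorded as attributes.  Field tables are plain TSV.
"""

from __future__ import annotations

from pathlib import Path
from typing import Tuple, Union

import h5py
import numpy as np
import pandas as pd

from .containers import Autocorr3D, RateMap, SpikeTrain, Trajectory

__all__ = [
    "write_trajectory_csv", "read_trajectory_csv",
    "write_spikes_csv", "read_spikes_csv",
    "write_session_h5", "read_session_h5",
    "write_ratemap_h5", "read_ratemap_h5",
    "write_autocorr_h5", "read_autocorr_h5",
    "fields_table",
]

PathLike = Union[str, Path]


def write_trajectory_csv(path: PathLike, traj: Trajectory) -> None:
    df = pd.DataFrame({"t": traj.t, "x": traj.pos[:, 0],
                       "y": traj.pos[:, 1], "z": traj.pos[:, 2]})
    df.to_csv(path, index=False)


def read_trajectory_csv(path: PathLike) -> Trajectory:
    df = pd.read_csv(path)
    return Trajectory(t=df["t"].to_numpy(),
                      pos=df[["x", "y", "z"]].to_numpy())


def write_spikes_csv(path: PathLike, spikes: SpikeTrain) -> None:
    pd.DataFrame({"t": spikes.times}).to_csv(path, index=False)


def read_spikes_csv(path: PathLike, cell_id: str = "cell") -> SpikeTrain:
    return SpikeTrain(times=pd.read_csv(path)["t"].to_numpy(),
                      cell_id=cell_id)


def write_session_h5(path: PathLike, traj: Trajectory,
                     spikes: SpikeTrain) -> None:
    with h5py.File(path, "w") as f:
        g = f.create_group("trajectory")
        g.create_dataset("t", data=traj.t)
        g.create_dataset("pos", data=traj.pos)
        g.attrs["units"] = "s, cm"
        s = f.create_group("spikes")
        s.create_dataset("times", data=spikes.times)
        s.attrs["cell_id"] = spikes.cell_id


def read_session_h5(path: PathLike) -> Tuple[Trajectory, SpikeTrain]:
    with h5py.File(path, "r") as f:
        traj = Trajectory(t=f["trajectory/t"][:], pos=f["trajectory/pos"][:])
        spikes = SpikeTrain(times=f["spikes/times"][:],
                            cell_id=str(f["spikes"].attrs.get("cell_id",
                                                              "cell")))
    return traj, spikes


def write_ratemap_h5(path: PathLike, ratemap: RateMap) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("rate", data=ratemap.rate)
        f.create_dataset("occupancy", data=ratemap.occupancy)
        f.create_dataset("spikes", data=ratemap.spikes)
        f.create_dataset("visited", data=ratemap.visited)
        f.attrs["voxel_size_cm"] = ratemap.voxel_size
        f.attrs["origin_cm"] = ratemap.origin
        f.attrs["axis_order"] = "xyz"
        f.attrs["sample_rate_hz"] = ratemap.sample_rate
        f.attrs["occupancy_unit"] = ratemap.occupancy_unit
        if ratemap.alpha is not None:
            f.attrs["alpha"] = ratemap.alpha


def read_ratemap_h5(path: PathLike) -> RateMap:
    with h5py.File(path, "r") as f:
        alpha = f.attrs.get("alpha")
        return RateMap(rate=f["rate"][:], occupancy=f["occupancy"][:],
                       spikes=f["spikes"][:],
                       voxel_size=float(f.attrs["voxel_size_cm"]),
                       origin=np.asarray(f.attrs["origin_cm"]),
                       visited=f["visited"][:].astype(bool),
                       sample_rate=float(f.attrs["sample_rate_hz"]),
                       alpha=float(alpha) if alpha is not None else None,
                       occupancy_unit=str(f.attrs["occupancy_unit"]))


def write_autocorr_h5(path: PathLike, ac: Autocorr3D) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("r", data=ac.r)
        f.create_dataset("n_overlap", data=ac.n_overlap)
        f.attrs["lag_voxel_cm"] = ac.voxel_size
        f.attrs["axis_order"] = "xyz"


def read_autocorr_h5(path: PathLike) -> Autocorr3D:
    with h5py.File(path, "r") as f:
        return Autocorr3D(r=f["r"][:], n_overlap=f["n_overlap"][:],
                          voxel_size=float(f.attrs["lag_voxel_cm"]))


def fields_table(fieldset) -> pd.DataFrame:
    """One row per detected field: centroid, volume, axes, elongation."""
    rows = []
    for f in fieldset:
        row = {"label": f.label,
               "cx_cm": f.centroid[0], "cy_cm": f.centroid[1],
               "cz_cm": f.centroid[2],
               "volume_cm3": f.volume, "convex_volume_cm3": f.convex_volume,
               "equivalent_diameter_cm": f.equivalent_diameter,
               "peak_rate_hz": f.peak_rate, "visits": f.visits,
               "elongation": f.elongation}
        if f.principal_axes is not None:
            row.update({"P1_cm": f.principal_axes[0],
                        "P2_cm": f.principal_axes[1],
                        "P3_cm": f.principal_axes[2]})
        rows.append(row)
    return pd.DataFrame(rows)
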