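"""HDF5 / TSV / JSON persistence for the shared data layout.

One HDF5 container per run:

    /lfp/data, /lfp/coords_mm, /lfp/fs           surface-grid LFP
    /gp/phase, /gp/amp, /gp/freq, /gp/mask       analytic field
    /events/touch_s                              touch times
    /calcium/dff, /calcium/deconv, /calcium/centroids, /calcium/frame_rate
    /laminar/data, /laminar/dz_um, /laminar/fs   linear-probe LFP

Wave tables go to TSV, ensembles to JSON sidecars, pose tables to TSV
(frame, label, x_px, y_px).
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .containers import AnalyticField, CalciumRaster, GridLFP, LaminarLFP

__all__ = [
    "save_grid_lfp", "load_grid_lfp",
    "save_analytic_field", "load_analytic_field",
    "save_calcium", "load_calcium",
    "save_laminar", "load_laminar",
    "save_touch_times", "load_touch_times",
    "save_wave_table", "load_wave_table",
    "save_ensembles_json", "save_pose_tsv", "load_pose_tsv",
]


def save_grid_lfp(path, lfp: GridLFP, mode: str = "a") -> None:
    with h5py.File(path, mode) as f:
        g = f.require_group("lfp")
        for name in ("data", "coords_mm"):
            if name in g:
                del g[name]
        g.create_dataset("data", data=lfp.data)
        g.create_dataset("coords_mm", data=lfp.coords)
        g.attrs["fs"] = lfp.fs
        g.attrs["t0"] = lfp.t0


def load_grid_lfp(path) -> GridLFP:
    with h5py.File(path, "r") as f:
        g = f["lfp"]
        return GridLFP(g["data"][()], g["coords_mm"][()],
                       float(g.attrs["fs"]), float(g.attrs.get("t0", 0.0)))


def save_analytic_field(path, field: AnalyticField, mode: str = "a") -> None:
    with h5py.File(path, mode) as f:
        g = f.require_group("gp")
        for name in ("phase", "amp", "freq", "mask", "coords_mm"):
            if name in g:
                del g[name]
        g.create_dataset("phase", data=field.phase)
        g.create_dataset("amp", data=field.amplitude)
        g.create_dataset("freq", data=field.freq)
        g.create_dataset("mask", data=field.mask)
        g.create_dataset("coords_mm", data=field.coords)
        g.attrs["fs"] = field.fs
        g.attrs["t0"] = field.t0


def load_analytic_field(path) -> AnalyticField:
    with h5py.File(path, "r") as f:
        g = f["gp"]
        return AnalyticField(
            g["phase"][()], g["amp"][()], g["freq"][()], g["mask"][()].astype(bool),
            g["coords_mm"][()], float(g.attrs["fs"]), float(g.attrs.get("t0", 0.0)),
        )


def save_calcium(path, raster: CalciumRaster, mode: str = "a") -> None:
    with h5py.File(path, mode) as f:
        g = f.require_group("calcium")
        for name in ("dff", "deconv", "centroids"):
            if name in g:
                del g[name]
        g.create_dataset("dff", data=raster.dff)
        g.create_dataset("deconv", data=raster.deconv)
        g.create_dataset("centroids", data=raster.centroids)
        g.attrs["frame_rate"] = raster.frame_rate
        g.attrs["t0"] = raster.t0


def load_calcium(path) -> CalciumRaster:
    with h5py.File(path, "r") as f:
        g = f["calcium"]
        return CalciumRaster(
            g["dff"][()], g["deconv"][()], g["centroids"][()],
            float(g.attrs["frame_rate"]), float(g.attrs.get("t0", 0.0)),
        )


def save_laminar(path, lam: LaminarLFP, mode: str = "a") -> None:
    with h5py.File(path, mode) as f:
        g = f.require_group("laminar")
        if "data" in g:
            del g["data"]
        g.create_dataset("data", data=lam.data)
        g.attrs["dz_um"] = lam.dz_um
        g.attrs["fs"] = lam.fs
        g.attrs["t0"] = lam.t0


def load_laminar(path) -> LaminarLFP:
    with h5py.File(path, "r") as f:
        g = f["laminar"]
        return LaminarLFP(g["data"][()], float(g.attrs["dz_um"]),
                          float(g.attrs["fs"]), float(g.attrs.get("t0", 0.0)))


def save_touch_times(path, touch_s, mode: str = "a") -> None:
    with h5py.File(path, mode) as f:
        g = f.require_group("events")
        if "touch_s" in g:
            del g["touch_s"]
        g.create_dataset("touch_s", data=np.asarray(touch_s, dtype=float))


def load_touch_times(path) -> np.ndarray:
    with h5py.File(path, "r") as f:
        return f["events/touch_s"][()]


def save_wave_table(path, frame: pd.DataFrame) -> None:
    frame.to_csv(path, sep="\t", index=False)


def load_wave_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def save_ensembles_json(path, ensembles) -> None:
    payload = []
    for e in ensembles:
        payload.append({
            "members": [int(m) for m in e.members],
            "rank": int(e.rank),
            "eigenvalue": float(e.eigenvalue),
            "n_connections": int(e.n_connections),
            "reactivation": float(e.reactivation),
            "node_strength": {str(k): float(v) for k, v in e.node_strength.items()},
            "weights": {f"{i}-{j}": float(w) for (i, j), w in e.weights.items()},
        })
    Path(path).write_text(json.dumps(payload, indent=1))


def save_pose_tsv(path, pose: pd.DataFrame) -> None:
    pose.to_csv(path, sep="\t", index=False)


def load_pose_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
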