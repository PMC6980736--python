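"""Run outputs: trajectory/event CSVs, legacy-VTK point-cloud snapshots
of the particle fields and HDF5 restart files."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .ecm import EcmDomain
from .fibers import FiberParams, SpringNetwork, von_mises_field

__all__ = ["write_vtk_points", "write_ecm_snapshot", "write_cell_snapshot",
           "save_restart", "load_restart_arrays"]


def write_vtk_points(path, points: np.ndarray, scalars: dict | None = None,
                     vectors: dict | None = None) -> None:
    """Minimal legacy-VTK (ASCII) point-cloud writer; 2D points are
    embedded at z = 0."""
    points = np.asarray(points, dtype=float)
    n = len(points)
    p3 = np.zeros((n, 3))
    p3[:, : points.shape[1]] = points
    lines = ["# vtk DataFile Version 3.0", "protrudesim snapshot", "ASCII",
             "DATASET POLYDATA", f"POINTS {n} float"]
    lines += [" ".join(f"{v:.6g}" for v in row) for row in p3]
    lines.append(f"POINT_DATA {n}")
    for name, arr in (scalars or {}).items():
        lines.append(f"SCALARS {name} float 1")
        lines.append("LOOKUP_TABLE default")
        lines += [f"{float(v):.6g}" for v in np.asarray(arr)]
    for name, arr in (vectors or {}).items():
        arr = np.asarray(arr, dtype=float)
        a3 = np.zeros((n, 3))
        a3[:, : arr.shape[1]] = arr
        lines.append(f"VECTORS {name} float")
        lines += [" ".join(f"{v:.6g}" for v in row) for row in a3]
    Path(path).write_text("\n".join(lines) + "\n")


def write_ecm_snapshot(path, domain: EcmDomain,
                       net: SpringNetwork | None = None,
                       fparams: FiberParams | None = None) -> None:
    sxx, syy, sxy = domain.sigma.T
    vm = np.sqrt(sxx**2 - sxx * syy + syy**2 + 3 * sxy**2)
    scal = {"f_degr": domain.f_degr, "rho": domain.rho,
            "sigma_xx": sxx, "sigma_yy": syy, "sigma_xy": sxy,
            "von_mises": vm}
    if net is not None and fparams is not None:
        scal["von_mises_fib"] = von_mises_field(net, domain, fparams)
    write_vtk_points(path, domain.x, scalars=scal,
                     vectors={"velocity": domain.v})


def write_cell_snapshot(path, cell) -> None:
    from .cell import cortex_curvature
    df = pd.DataFrame({
        "id": np.arange(cell.n),
        "x": cell.x[:, 0], "y": cell.x[:, 1],
        "front": cell.front.astype(int),
        "protrusion_id": cell.protrusion_id,
        "f_mat": cell.f_mat,
        "kappa": cortex_curvature(cell),
    })
    df.to_csv(path, index=False)


def save_restart(path, state) -> None:
    """HDF5 restart snapshot of every field needed to reproduce the
    trajectory bit-for-bit on the same build."""
    with h5py.File(path, "w") as f:
        f.attrs["t"] = state.t
        f.attrs["step_count"] = state.step_count
        g = f.create_group("ecm")
        for k in ("x", "x0", "v", "m", "rho", "sigma", "f_degr", "f_body"):
            g.create_dataset(k, data=getattr(state.ecm, k))
        g.create_dataset("fixed", data=state.ecm.fixed)
        c = f.create_group("cell")
        for k in ("x", "v", "l0", "k_seg", "f_mat", "drag_mult",
                  "protrusion_id", "front"):
            c.create_dataset(k, data=getattr(state.cell, k))
        f.create_dataset("v_ecm", data=state.v_ecm)
        f.attrs["rng_state"] = json.dumps(state.rng.bit_generator.state)


def load_restart_arrays(path) -> dict:
    out = {}
    with h5py.File(path, "r") as f:
        out["t"] = float(f.attrs["t"])
        out["step_count"] = int(f.attrs["step_count"])
        out["ecm"] = {k: f["ecm"][k][...] for k in f["ecm"]}
        out["cell"] = {k: f["cell"][k][...] for k in f["cell"]}
        out["v_ecm"] = f["v_ecm"][...]
        out["rng_state"] = json.loads(f.attrs["rng_state"])
    return out
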