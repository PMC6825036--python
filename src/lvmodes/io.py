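"""Result serialization: CSV time series, PV loop, VTK shapes, manifest."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .dynamics import CardiacCycleResult
from .geometry import QuadratureGrid, ReferenceDomain
from .kinematics import KinematicsEngine
from .modes import ModeBasisSpec

__all__ = ["write_results", "write_vtk_shape", "timeseries_frame"]


def timeseries_frame(result: CardiacCycleResult) -> pd.DataFrame:
    cols = {"t": result.time}
    for j in range(result.q.shape[1]):
        cols[f"q{j+1}"] = result.q[:, j]
    cols["P_lv"] = result.P_lv
    cols["V_lv"] = result.V_lv
    cols["q_mv"] = result.q_mv
    cols["q_aov"] = result.q_aov
    cols["P_art"] = result.P_art
    return pd.DataFrame(cols)


def write_vtk_shape(path, dom: ReferenceDomain, basis: ModeBasisSpec, q,
                    n_mu=3, n_nu=15, n_phi=24, point_data=None):
    """Deformed (or reference, q = 0) wall shape as a legacy ASCII VTK
    unstructured grid of hexahedral cells on the parametric lattice."""
    grid = QuadratureGrid.build(dom, n_mu=n_mu, n_nu=n_nu, n_phi=n_phi)
    eng = KinematicsEngine(dom, basis, grid.mu0, grid.nu0, grid.phi0)
    x = np.real(eng.positions(np.asarray(q, float)))
    nm, nn, np_ = grid.shape

    def vid(i, j, k):
        return (i * nn + j) * np_ + (k % np_)

    cells = []
    for i in range(nm - 1):
        for j in range(nn - 1):
            for k in range(np_):
                cells.append([
                    vid(i, j, k), vid(i + 1, j, k),
                    vid(i + 1, j + 1, k), vid(i, j + 1, k),
                    vid(i, j, k + 1), vid(i + 1, j, k + 1),
                    vid(i + 1, j + 1, k + 1), vid(i, j + 1, k + 1),
                ])
    lines = [
        "# vtk DataFile Version 3.0",
        "lvmodes deformed wall",
        "ASCII",
        "DATASET UNSTRUCTURED_GRID",
        f"POINTS {x.shape[0]} float",
    ]
    lines += [" ".join(f"{v:.6g}" for v in row) for row in x]
    lines.append(f"CELLS {len(cells)} {9 * len(cells)}")
    lines += ["8 " + " ".join(map(str, c)) for c in cells]
    lines.append(f"CELL_TYPES {len(cells)}")
    lines += ["12"] * len(cells)
    if point_data:
        lines.append(f"POINT_DATA {x.shape[0]}")
        for name, vals in point_data.items():
            lines.append(f"SCALARS {name} float 1")
            lines.append("LOOKUP_TABLE default")
            lines += [f"{v:.6g}" for v in np.asarray(vals)]
    Path(path).write_text("\n".join(lines) + "\n")


def write_results(result: CardiacCycleResult, out_dir, dom=None, basis=None,
                  config=None, config_digest=None, seed=None,
                  vtk_every=0):
    """Write timeseries.csv, pvloop.csv, manifest.json and optional VTK
    snapshots (every ``vtk_every``-th recorded step) into ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    df = timeseries_frame(result)
    df.to_csv(out / "timeseries.csv", index=False)
    pd.DataFrame({"V_lv": result.V_lv, "P_lv": result.P_lv}).to_csv(
        out / "pvloop.csv", index=False)

    manifest = {
        "package": "lvmodes",
        "version": __version__,
        "config_hash": config_digest,
        "seed": seed,
        "mode_ordering": result.mode_ordering,
        "period_s": result.period,
        "stroke_work_J": result.stroke_work(),
        "stroke_volume_mL": result.stroke_volume(),
        "config": config,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))

    if vtk_every and dom is not None and basis is not None:
        for m in range(0, len(result.time), vtk_every):
            write_vtk_shape(out / f"shape_{m:05d}.vtk", dom, basis,
                            result.q[m])
    return out
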