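"""Output writers: legacy-ASCII VTK fields, CSV time series, run manifest.

The VTK writer emits unstructured grids of hexahedral cells (the spherical
mesh's (r, theta, phi) bricks) with cell-centered scalar arrays, readable
by standard viewers.  Time series go through pandas to CSV with SI-unit
column names; the manifest records the configuration hash, package version
and seed so a run can be regenerated from it.
"""

from __future__ import annotations

import json
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from .dcm.mesh import ContinuumMesh

__all__ = ["write_vtk", "write_timeseries", "write_manifest", "write_results"]


def write_vtk(mesh: ContinuumMesh, cell_data: dict[str, np.ndarray],
              path: str | Path, title: str = "lungflow fields") -> None:
    """Write cell-centered fields on the spherical mesh as legacy VTK."""
    points, conn = mesh.cell_corners()
    for name, arr in cell_data.items():
        if len(arr) != mesh.n_cells:
            raise ValueError(
                f"array {name!r} has {len(arr)} values for {mesh.n_cells} cells")
    lines = [
        "# vtk DataFile Version 3.0",
        title,
        "ASCII",
        "DATASET UNSTRUCTURED_GRID",
        f"POINTS {len(points)} double",
    ]
    lines += [" ".join(f"{c:.9e}" for c in p) for p in points]
    lines.append(f"CELLS {len(conn)} {len(conn) * 9}")
    lines += ["8 " + " ".join(str(i) for i in c) for c in conn]
    lines.append(f"CELL_TYPES {len(conn)}")
    lines += ["12"] * len(conn)  # VTK_HEXAHEDRON
    lines.append(f"CELL_DATA {mesh.n_cells}")
    for name, arr in cell_data.items():
        lines.append(f"SCALARS {name} double 1")
        lines.append("LOOKUP_TABLE default")
        lines += [f"{v:.9e}" for v in np.asarray(arr, dtype=float)]
    Path(path).write_text("\n".join(lines) + "\n")


def write_timeseries(records: list[dict], path: str | Path,
                     columns: list[str] | None = None) -> None:
    """Write record dicts as CSV (header row always present)."""
    df = pd.DataFrame.from_records(records, columns=columns)
    df.to_csv(path, index=False)


def write_manifest(config, path: str | Path, seed: int | None = None,
                   extra: dict | None = None) -> dict:
    from . import __version__

    manifest = {
        "package": "lungflow",
        "version": __version__,
        "config_hash": config.config_hash(),
        "seed": seed,
        "created_utc": datetime.now(timezone.utc).isoformat(),
        "config": config.model_dump(mode="json"),
    }
    if extra:
        manifest.update(extra)
    Path(path).write_text(json.dumps(manifest, indent=1))
    return manifest


def write_results(results, outdir: str | Path, seed: int | None = None) -> None:
    """Write a coupled run's full results bundle."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    audit = results.audit()
    write_manifest(results.config, outdir / "manifest.json", seed=seed, extra={
        "n_steps": results.n_steps,
        "audit": audit,
        "effective_resistances_pa_s_per_m3": {
            str(nid): un.R_eff for nid, un in results.nodes.items()},
    })
    write_timeseries(
        results.graph_series, outdir / "graph_timeseries.csv",
        columns=["time", "node_id", "pressure_pa", "mole_fraction"])
    write_timeseries(
        results.node_series, outdir / "upscaled_timeseries.csv",
        columns=["time", "node_id", "kind", "q_x_mol_per_s",
                 "q_mass_kg_per_s", "tissue_moles", "bound_moles",
                 "extracted_moles"])
    for nid, un in results.nodes.items():
        if un.state is None:
            continue
        data = {
            "tissue_pressure_pa": un.state.p_t,
            "capillary_pressure_pa": un.state.p_c,
            "tissue_mole_fraction": un.state.x_t,
            "capillary_mole_fraction": un.state.x_c,
        }
        if un.state.C_RL is not None:
            data["receptor_complex_mol_per_m3"] = un.state.C_RL
        write_vtk(un.model.mesh, data,
                  outdir / f"alveolus_{nid}_{un.kind}.vtk",
                  title=f"upscaled node {nid} ({un.kind})")
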