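"""Export of meshes, fields and results to standard text formats.

Fields go to ASCII VTU (VTK XML unstructured grid, tetra cells) readable by
ParaView/VTK; curves and datasets to CSV; results and provenance to JSON.
"""

from __future__ import annotations

import hashlib
import json
from typing import Dict, Optional

import numpy as np

from .fem import FieldSolution
from .geometry import Mesh

try:  # single source of the installed version
    from importlib.metadata import version as _pkg_version

    __pkg_version__ = _pkg_version("epfem")
except Exception:  # pragma: no cover
    __pkg_version__ = "unknown"


def _ascii(arr: np.ndarray, fmt: str = "%.9g") -> str:
    return "\n".join(" ".join(fmt % v for v in np.atleast_1d(row))
                     for row in np.atleast_2d(arr))


def write_vtu(path, mesh: Mesh,
              point_data: Optional[Dict[str, np.ndarray]] = None,
              cell_data: Optional[Dict[str, np.ndarray]] = None) -> None:
    """Write the mesh (plus optional nodal/element fields) as ASCII VTU."""
    point_data = point_data or {}
    cell_data = cell_data or {}
    n, m = mesh.n_nodes, mesh.n_elements
    lines = [
        '<?xml version="1.0"?>',
        '<VTKFile type="UnstructuredGrid" version="0.1" byte_order="LittleEndian">',
        "<UnstructuredGrid>",
        f'<Piece NumberOfPoints="{n}" NumberOfCells="{m}">',
        "<Points>",
        '<DataArray type="Float64" NumberOfComponents="3" format="ascii">',
        _ascii(mesh.points),
        "</DataArray>",
        "</Points>",
        "<Cells>",
        '<DataArray type="Int64" Name="connectivity" format="ascii">',
        _ascii(mesh.tets, fmt="%d"),
        "</DataArray>",
        '<DataArray type="Int64" Name="offsets" format="ascii">',
        _ascii(4 * np.arange(1, m + 1), fmt="%d"),
        "</DataArray>",
        '<DataArray type="UInt8" Name="types" format="ascii">',
        _ascii(np.full(m, 10), fmt="%d"),  # 10 = VTK_TETRA
        "</DataArray>",
        "</Cells>",
    ]
    lines.append("<PointData>")
    for name, arr in point_data.items():
        lines += [
            f'<DataArray type="Float64" Name="{name}" format="ascii">',
            _ascii(np.asarray(arr, dtype=float)),
            "</DataArray>",
        ]
    lines.append("</PointData>")
    lines.append("<CellData>")
    for name, arr in cell_data.items():
        arr = np.asarray(arr)
        ncomp = 1 if arr.ndim == 1 else arr.shape[1]
        lines += [
            f'<DataArray type="Float64" Name="{name}" '
            f'NumberOfComponents="{ncomp}" format="ascii">',
            _ascii(arr.astype(float)),
            "</DataArray>",
        ]
    lines.append("</CellData>")
    lines += ["</Piece>", "</UnstructuredGrid>", "</VTKFile>"]
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def export_solution_vtu(path, sol: FieldSolution) -> None:
    """Field solution to VTU: nodal phi [V]; per-element |E| [V/cm], region."""
    sig = sol.sigma_elem
    sig_mean = sig if sig.ndim == 1 else np.einsum("eii->e", sig) / 3.0
    write_vtu(
        path,
        sol.mesh,
        point_data={"phi_V": sol.phi},
        cell_data={
            "E_V_per_cm": sol.E_mag_vcm,
            "region_id": sol.mesh.region_ids.astype(float),
            "sigma_mean_S_per_m": sig_mean,
        },
    )


def save_json(path, obj) -> None:
    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        raise TypeError(f"not JSON serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=default)
        fh.write("\n")


def provenance_record(config: dict, seed: Optional[int] = None) -> dict:
    """Reproducibility record: config hash, package version, seed."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return {
        "config": config,
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "epfem_version": __pkg_version__,
        "seed": seed,
    }
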