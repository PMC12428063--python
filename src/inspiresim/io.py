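"""File plumbing: mesh/field export and run manifests.

Meshes and fields are exported as legacy-VTK ASCII (readable by ParaView
and friends); tables as CSV; manifests as JSON with SHA-256 hashes of
every written artifact.
"""

from __future__ import annotations

import hashlib
import json
import platform
from pathlib import Path

import numpy as np

from .mesh import Mesh


def write_vtk(mesh: Mesh, path, point_data: dict | None = None,
              cell_data: dict | None = None, title: str = "inspiresim") -> Path:
    """Write the (r, z) mesh with optional nodal/element scalars."""
    path = Path(path)
    lines = ["# vtk DataFile Version 3.0", title, "ASCII",
             "DATASET UNSTRUCTURED_GRID",
             f"POINTS {mesh.n_points} double"]
    for r, z in mesh.points:
        lines.append(f"{r:.9g} {z:.9g} 0")
    lines.append(f"CELLS {mesh.n_triangles} {4 * mesh.n_triangles}")
    for a, b, c in mesh.triangles:
        lines.append(f"3 {a} {b} {c}")
    lines.append(f"CELL_TYPES {mesh.n_triangles}")
    lines.extend(["5"] * mesh.n_triangles)

    def scalars(name, arr):
        out = [f"SCALARS {name} double 1", "LOOKUP_TABLE default"]
        out.extend(f"{v:.9g}" for v in np.asarray(arr, dtype=float))
        return out

    if point_data:
        lines.append(f"POINT_DATA {mesh.n_points}")
        for name, arr in point_data.items():
            lines.extend(scalars(name, arr))
    if cell_data:
        lines.append(f"CELL_DATA {mesh.n_triangles}")
        for name, arr in cell_data.items():
            lines.extend(scalars(name, arr))
    path.write_text("\n".join(lines) + "\n")
    return path


def file_sha256(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_manifest(run_dir, parameters: dict, seed=None,
                   status: str = "complete") -> Path:
    """Hash every artifact in ``run_dir`` and record parameters/versions."""
    run_dir = Path(run_dir)
    from . import __version__
    files = sorted(p for p in run_dir.rglob("*")
                   if p.is_file() and p.name != "manifest.json")
    manifest = {
        "status": status,
        "seed": seed,
        "parameters": parameters,
        "versions": {"inspiresim": __version__,
                     "python": platform.python_version(),
                     "numpy": np.__version__},
        "outputs": {str(p.relative_to(run_dir)): file_sha256(p)
                    for p in files},
    }
    out = run_dir / "manifest.json"
    out.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return out
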