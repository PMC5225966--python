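"""Writers: VTK legacy unstructured grids, ECG CSV, biomarker JSON, manifests.

The VTK writer emits the legacy ASCII unstructured-grid format with the
mesh labels and (optionally) activation times as point data, readable by
ParaView and friends.  All writers are deterministic: writing the same
result twice yields byte-identical files, which the manifest checksums
make easy to verify.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .biomarkers import QRSBiomarkers
from .forward import ECG12, LEAD_NAMES
from .geometry import BiventricularMesh

__all__ = [
    "write_vtk",
    "write_ecg_csv",
    "write_activation_csv",
    "write_biomarkers_json",
    "write_manifest",
]


def write_vtk(
    mesh: BiventricularMesh,
    path: str | Path,
    point_data: dict[str, np.ndarray] | None = None,
) -> Path:
    """Write the mesh as a legacy-ASCII VTK unstructured grid.

    Region/side labels and anatomical coordinates are always included;
    extra per-node scalar arrays (e.g. activation times) may be supplied
    via ``point_data``.
    """
    path = Path(path)
    n = mesh.n_nodes
    cells = mesh.elements
    data = {
        "region": mesh.region.astype(float),
        "apicobasal": mesh.a,
        "transmural": mesh.m,
        "rotational": mesh.theta,
    }
    for label, mask in mesh.surface.items():
        data[f"surface_{label}"] = mask.astype(float)
    if point_data:
        for k, v in point_data.items():
            arr = np.asarray(v, dtype=float)
            if arr.shape != (n,):
                raise ValueError(f"point data {k!r} must have shape ({n},)")
            data[k] = arr

    lines = [
        "# vtk DataFile Version 3.0",
        "qrsim biventricular mesh",
        "ASCII",
        "DATASET UNSTRUCTURED_GRID",
        f"POINTS {n} float",
    ]
    lines += [" ".join(f"{x:.6g}" for x in p) for p in mesh.nodes]
    lines.append(f"CELLS {len(cells)} {len(cells) * 9}")
    lines += ["8 " + " ".join(str(i) for i in c) for c in cells]
    lines.append(f"CELL_TYPES {len(cells)}")
    lines += ["12"] * len(cells)  # VTK_HEXAHEDRON
    lines.append(f"POINT_DATA {n}")
    for name, arr in data.items():
        lines.append(f"SCALARS {name} float 1")
        lines.append("LOOKUP_TABLE default")
        lines += [f"{x:.6g}" for x in arr]
    path.write_text("\n".join(lines) + "\n")
    return path


def write_ecg_csv(ecg: ECG12, path: str | Path) -> Path:
    """CSV with header time_ms, I, II, ..., V6."""
    path = Path(path)
    df = pd.DataFrame({"time_ms": ecg.time})
    for name in LEAD_NAMES:
        df[name] = ecg.leads[name]
    df.to_csv(path, index=False, float_format="%.6g")
    return path


def write_activation_csv(t_act: np.ndarray, path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame({"node": np.arange(len(t_act)), "t_act_ms": t_act})
    df.to_csv(path, index=False, float_format="%.6g")
    return path


def write_biomarkers_json(
    bm: QRSBiomarkers, path: str | Path, labels: set[str] | None = None
) -> Path:
    path = Path(path)
    payload = {
        "qrs_onset_ms": bm.onset,
        "qrs_offset_ms": bm.offset,
        "qrs_width_ms": bm.width,
        "frontal_axis_deg": bm.axis,
        "late_axis_deg": bm.late_axis,
        "leads": {k: dataclasses.asdict(v) for k, v in bm.per_lead.items()},
    }
    if labels is not None:
        payload["classification"] = sorted(labels)
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    return path


def write_manifest(directory: str | Path, files: list[Path]) -> Path:
    """Manifest of written artifacts with SHA-256 content checksums."""
    directory = Path(directory)
    entries = []
    for f in sorted(files):
        digest = hashlib.sha256(Path(f).read_bytes()).hexdigest()
        entries.append({"file": Path(f).name, "sha256": digest})
    path = directory / "manifest.json"
    path.write_text(json.dumps(entries, indent=2) + "\n")
    return path
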