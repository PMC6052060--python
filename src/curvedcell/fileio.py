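"""File formats: PLY/OFF meshes, CSV tables, TIFF images, fit JSON.

Mesh reading goes through trimesh (PLY binary/ASCII and OFF).  PLY writing
uses an in-package ASCII emitter with double-precision vertex properties so
that a written mesh reads back with bit-identical coordinates; per-face
intensity is stored either as a named float property on the PLY faces or
as a CSV sidecar keyed by 0-based face index.  Unwrapped images are
written as 16-bit TIFF with an accompanying JSON carrying the nm-per-pixel
scale.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import trimesh

from .geometry import CellSurface, validate_mesh

FORMAT_VERSION = 1


def write_ply(
    mesh: trimesh.Trimesh,
    path,
    face_intensity: np.ndarray | None = None,
) -> Path:
    """Write an ASCII PLY with float64 coordinates (lossless round-trip)."""
    path = Path(path)
    v = np.asarray(mesh.vertices, dtype=float)
    f = np.asarray(mesh.faces, dtype=int)
    lines = [
        "ply",
        "format ascii 1.0",
        f"comment curvedcell v{FORMAT_VERSION}",
        f"element vertex {len(v)}",
        "property double x",
        "property double y",
        "property double z",
        f"element face {len(f)}",
        "property list uchar int vertex_indices",
    ]
    if face_intensity is not None:
        if len(face_intensity) != len(f):
            raise ValueError("face_intensity length mismatch")
        lines.append("property double intensity")
    lines.append("end_header")
    for p in v:
        lines.append(f"{p[0]:.17g} {p[1]:.17g} {p[2]:.17g}")
    if face_intensity is None:
        for t in f:
            lines.append(f"3 {t[0]} {t[1]} {t[2]}")
    else:
        for t, i in zip(f, face_intensity):
            lines.append(f"3 {t[0]} {t[1]} {t[2]} {i:.17g}")
    path.write_text("\n".join(lines) + "\n")
    return path


def read_mesh(path) -> tuple[trimesh.Trimesh, np.ndarray | None]:
    """Read a PLY or OFF mesh; returns (mesh, face_intensity or None)."""
    path = Path(path)
    mesh = trimesh.load(path, process=False, force="mesh")
    intensity = None
    md = getattr(mesh, "metadata", {}) or {}
    ply_raw = md.get("_ply_raw")
    if ply_raw and "face" in ply_raw and "intensity" in ply_raw["face"].get("data", {}):
        intensity = np.asarray(
            ply_raw["face"]["data"]["intensity"], dtype=float
        ).ravel()
    return trimesh.Trimesh(
        vertices=np.asarray(mesh.vertices, dtype=float),
        faces=np.asarray(mesh.faces, dtype=int),
        process=False,
    ), intensity


def write_off(mesh: trimesh.Trimesh, path) -> Path:
    path = Path(path)
    path.write_bytes(trimesh.exchange.off.export_off(mesh).encode())
    return path


def save_cell(cell: CellSurface, directory, sidecar: bool = True) -> dict:
    """Write a cell as PLY (+ CSV intensity sidecar) under ``directory``.

    Returns a manifest entry with the written paths.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    ply = directory / f"{cell.cell_id}.ply"
    if sidecar or cell.face_intensity is None:
        write_ply(cell.mesh, ply)
    else:
        write_ply(cell.mesh, ply, face_intensity=cell.face_intensity)
    entry = {"cell_id": cell.cell_id, "ply": str(ply)}
    if cell.face_intensity is not None and sidecar:
        csv = directory / f"{cell.cell_id}_intensity.csv"
        pd.DataFrame(
            {
                "face_index": np.arange(len(cell.face_intensity)),
                "intensity": cell.face_intensity,
            }
        ).to_csv(csv, index=False, float_format="%.17g")
        entry["intensity_csv"] = str(csv)
    if cell.cytoplasmic_total:
        meta = directory / f"{cell.cell_id}_meta.json"
        meta.write_text(
            json.dumps({"cytoplasmic_total": cell.cytoplasmic_total}, indent=1)
        )
        entry["meta_json"] = str(meta)
    return entry


def load_cell(ply_path, intensity_csv=None) -> CellSurface:
    """Load a cell from PLY (+ optional CSV intensity sidecar)."""
    ply_path = Path(ply_path)
    mesh, intensity = read_mesh(ply_path)
    mesh = validate_mesh(mesh)
    if intensity_csv is None:
        candidate = ply_path.with_name(ply_path.stem + "_intensity.csv")
        intensity_csv = candidate if candidate.exists() else None
    if intensity_csv is not None:
        df = pd.read_csv(intensity_csv, float_precision="round_trip")
        intensity = (
            df.sort_values("face_index")["intensity"].to_numpy(dtype=float)
        )
        if len(intensity) != len(mesh.faces):
            raise ValueError(
                f"intensity sidecar has {len(intensity)} rows for "
                f"{len(mesh.faces)} faces"
            )
    cyto = 0.0
    meta_json = ply_path.with_name(ply_path.stem + "_meta.json")
    if meta_json.exists():
        cyto = float(json.loads(meta_json.read_text()).get("cytoplasmic_total", 0.0))
    return CellSurface(
        mesh=mesh,
        face_intensity=intensity,
        cell_id=ply_path.stem,
        cytoplasmic_total=cyto,
    )


def write_tiff(image: np.ndarray, path, nm_per_px: float) -> Path:
    """Write a 16-bit TIFF plus a JSON with the physical pixel scale."""
    path = Path(path)
    img = np.asarray(image, dtype=float)
    lo, hi = float(img.min()), float(img.max())
    scale = (65535.0 / (hi - lo)) if hi > lo else 1.0
    data = np.round((img - lo) * scale).astype(np.uint16)
    tifffile.imwrite(path, data)
    meta = {
        "version": FORMAT_VERSION,
        "nm_per_px": nm_per_px,
        "offset": lo,
        "scale": scale,
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))
    return path


def read_tiff(path) -> tuple[np.ndarray, dict]:
    """Read a 16-bit TIFF written by :func:`write_tiff`, undoing the scaling."""
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    if meta.get("version", 0) > FORMAT_VERSION:
        raise ValueError(
            f"file {path} was written by a newer format version {meta['version']}"
        )
    data = tifffile.imread(path).astype(float)
    return data / meta["scale"] + meta["offset"], meta


def save_fit_json(results, path) -> Path:
    """Serialise a fitted ΔIDD model so predictions can be reproduced."""
    path = Path(path)
    payload = {"version": FORMAT_VERSION, **results.to_dict()}
    path.write_text(json.dumps(payload, indent=1))
    return path


def load_fit_json(path) -> dict:
    path = Path(path)
    payload = json.loads(path.read_text())
    if payload.get("version", 0) > FORMAT_VERSION:
        raise ValueError("fit file written by a newer format version")
    return payload


def predict_from_fit(payload: dict, delta_features: pd.DataFrame) -> np.ndarray:
    """Re-predict ΔIDD from a saved fit payload (deterministic)."""
    cols = payload["columns"]
    missing = [c for c in cols if c not in delta_features.columns]
    if missing:
        raise ValueError(f"missing features: {missing}")
    X = delta_features[cols].to_numpy(dtype=float)
    beta = np.asarray(payload["beta_standardized"], dtype=float)
    scale = np.asarray(payload["col_scale"], dtype=float)
    return (X / scale) @ beta + payload["intercept"]
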