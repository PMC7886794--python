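"""File formats: NIfTI volumes, PLY surfaces, CSV tables, JSON sidecars.

NIfTI affines encode the grid convention directly: world (mm) =
``diag(spacing) @ index + 0.5 * spacing``, so voxel centres sit at
``(index + 0.5) * spacing``. Velocity fields are stored either as one
5-D volume ``(nx, ny, nz, nt, 3)`` or as three 4-D component volumes
(``*_vx/vy/vz``); both dialects are read back transparently.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .core import LumenSurface, VelocityField


def _affine(spacing):
    spacing = np.asarray(spacing, dtype=float)
    aff = np.diag(np.append(spacing, 1.0))
    aff[:3, 3] = 0.5 * spacing
    return aff


def _spacing_from(img) -> np.ndarray:
    return np.asarray(img.header.get_zooms()[:3], dtype=float)


def save_mask(mask: np.ndarray, spacing, path):
    nib.save(nib.Nifti1Image(np.asarray(mask, dtype=np.uint8),
                             _affine(spacing)), str(path))


def load_mask(path):
    img = nib.load(str(path))
    return np.asarray(img.dataobj).astype(np.uint8), _spacing_from(img)


def save_velocity(field: VelocityField, path, split_components: bool = False):
    """Write a velocity field (5-D dialect, or three 4-D volumes)."""
    path = Path(path)
    meta = {"times_s": field.times.tolist(), "cycle_s": field.cycle}
    if split_components:
        stem = path.name.replace(".nii.gz", "").replace(".nii", "")
        for c, ax in enumerate("xyz"):
            img = nib.Nifti1Image(
                np.ascontiguousarray(field.data[..., c]).astype(np.float32),
                _affine(field.spacing))
            nib.save(img, str(path.parent / f"{stem}_v{ax}.nii.gz"))
        sidecar = path.parent / f"{stem}_timing.json"
    else:
        img = nib.Nifti1Image(field.data.astype(np.float32),
                              _affine(field.spacing))
        nib.save(img, str(path))
        sidecar = path.with_name(path.name.split(".")[0] + "_timing.json")
    sidecar.write_text(json.dumps(meta))


def load_velocity(path) -> VelocityField:
    """Read either velocity dialect; timing comes from the JSON sidecar."""
    path = Path(path)
    stem = path.name.replace(".nii.gz", "").replace(".nii", "")
    comp = path.parent / f"{stem}_vx.nii.gz"
    if path.exists():
        img = nib.load(str(path))
        data = np.asarray(img.dataobj, dtype=np.float64)
        spacing = _spacing_from(img)
    elif comp.exists():
        vols = []
        for ax in "xyz":
            img = nib.load(str(path.parent / f"{stem}_v{ax}.nii.gz"))
            vols.append(np.asarray(img.dataobj, dtype=np.float64))
        data = np.stack(vols, axis=-1)
        spacing = _spacing_from(img)
    else:
        raise FileNotFoundError(f"no velocity volume at {path}")
    sidecar = path.parent / f"{stem}_timing.json"
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else None
    nt = data.shape[3]
    times = np.asarray(meta["times_s"]) if meta else np.arange(nt) / nt
    cycle = meta["cycle_s"] if meta else 1.0
    return VelocityField(data, spacing, times, cycle)


def save_scalar_volume(vol: np.ndarray, spacing, path):
    nib.save(nib.Nifti1Image(np.asarray(vol, dtype=np.float32),
                             _affine(spacing)), str(path))


def load_scalar_volume(path):
    img = nib.load(str(path))
    return np.asarray(img.dataobj, dtype=np.float64), _spacing_from(img)


def save_truth(truth: dict, path):
    def clean(o):
        if isinstance(o, dict):
            return {str(k): clean(v) for k, v in o.items()}
        if isinstance(o, (list, tuple)):
            return [clean(v) for v in o]
        if isinstance(o, np.generic):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        return o
    Path(path).write_text(json.dumps(clean(truth), indent=2))


def load_truth(path) -> dict:
    return json.loads(Path(path).read_text())


def save_surface_ply(surface: LumenSurface, path):
    """ASCII PLY with per-vertex inward normal, area and branch label."""
    v, f = surface.vertices, surface.faces
    lines = [
        "ply", "format ascii 1.0",
        f"element vertex {len(v)}",
        "property float x", "property float y", "property float z",
        "property float nx", "property float ny", "property float nz",
        "property float area", "property int label",
        f"element face {len(f)}",
        "property list uchar int vertex_indices",
        "end_header",
    ]
    for p, n, a, lab in zip(v, surface.normals, surface.areas,
                            surface.labels):
        lines.append(f"{p[0]:.6f} {p[1]:.6f} {p[2]:.6f} "
                     f"{n[0]:.6f} {n[1]:.6f} {n[2]:.6f} {a:.8f} {int(lab)}")
    for tri in f:
        lines.append(f"3 {tri[0]} {tri[1]} {tri[2]}")
    Path(path).write_text("\n".join(lines) + "\n")


def save_centerlines_csv(centerlines, path):
    from .core import BRANCH_NAMES
    rows = []
    for lab, pts in centerlines.points.items():
        dia = centerlines.diameters[lab]
        for i, (p, d) in enumerate(zip(pts, dia)):
            rows.append({"branch": BRANCH_NAMES.get(lab, str(lab)),
                         "order": i, "x_mm": p[0], "y_mm": p[1],
                         "z_mm": p[2], "diameter_mm": d})
    pd.DataFrame(rows).to_csv(path, index=False)
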