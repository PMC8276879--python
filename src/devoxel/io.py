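"""NIfTI and sidecar I/O helpers shared by the CLI and pipeline."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from devoxel.asl_cbf import CbfMap


def save_nifti(data: np.ndarray, path, voxel_dims=(3.0, 3.0, 7.0),
               dtype=np.float32) -> None:
    data = np.asarray(data, dtype=dtype)
    affine = np.diag(list(voxel_dims[:3]) + [1.0])
    img = nib.Nifti1Image(data, affine)
    zooms = (tuple(voxel_dims) + (1.0,) * data.ndim)[: data.ndim]
    img.header.set_zooms(zooms)
    nib.save(img, str(path))


def load_nifti(path) -> tuple[np.ndarray, tuple[float, ...]]:
    img = nib.load(str(path))
    return np.asarray(img.dataobj, dtype=np.float64), tuple(
        float(z) for z in img.header.get_zooms()[:3]
    )


def voxel_volume_of(path) -> float:
    _, dims = load_nifti(path)
    return float(np.prod(dims))


def save_cbf_map(cbf: CbfMap, path, voxel_dims, sidecar: dict | None = None) -> None:
    """Write a CBF map (NaN outside the valid mask) plus a JSON sidecar."""
    save_nifti(cbf.values, path, voxel_dims)
    meta = {
        "units": "ml/100g/min",
        "gm_corrected": cbf.gm_corrected,
        "gm_threshold_used": cbf.gm_threshold_used,
        "subject_id": cbf.subject_id,
        "n_negative_voxels": cbf.n_negative,
        "n_valid_voxels": int(cbf.valid_mask.sum()),
    }
    if sidecar:
        meta.update(sidecar)
    Path(str(path) + ".json").write_text(json.dumps(meta, indent=2))


def load_cbf_map(path, subject_id: str | None = None) -> CbfMap:
    data, _ = load_nifti(path)
    valid = np.isfinite(data)
    sidecar = Path(str(path) + ".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return CbfMap(
        values=np.where(valid, data, np.nan),
        valid_mask=valid,
        gm_corrected=bool(meta.get("gm_corrected", False)),
        gm_threshold_used=meta.get("gm_threshold_used"),
        subject_id=subject_id or meta.get("subject_id") or Path(path).stem,
    )
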