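"""Readers and writers: NIfTI volumes, FSL bval/bvec, coil models, QC.

Conventions
-----------
- b-values: ms/um^2 internally; files with values > 100 are treated as
  s/mm^2 and divided by 1000 (logged). No physiological b sits near the
  threshold in either unit.
- bvec files are the FSL dialect (3 rows x N columns). By default the
  directions are interpreted in image coordinates and rotated into the
  scanner frame with the (orthonormalized) affine rotation; pass
  ``frame="scanner"`` to skip.
- L-field NIfTI: 4-D volume with 9 components in row-major order
  (Lxx, Lxy, Lxz, Lyx, ..., Lzz).
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path

import nibabel as nib
import numpy as np

from .gnl import CoilHarmonicModel, GradientCoilTensorField, NominalProtocol, VoxelGrid

__all__ = [
    "read_dwi",
    "write_dwi",
    "read_bvals_bvecs",
    "write_bvals_bvecs",
    "read_lfield",
    "write_lfield",
    "read_coilmodel",
    "write_coilmodel",
    "write_map",
    "write_provenance",
]

log = logging.getLogger("pipedmri")

B_UNIT_THRESHOLD = 100.0  # above this, bvals are s/mm^2


def read_bvals_bvecs(bval_path: str, bvec_path: str) -> tuple[np.ndarray, np.ndarray]:
    """FSL-dialect bval/bvec files -> (b (K,) in ms/um^2, g (K, 3))."""
    b = np.loadtxt(bval_path, ndmin=1).ravel()
    g = np.loadtxt(bvec_path, ndmin=2)
    if g.shape[0] == 3 and g.shape[1] != 3:
        g = g.T
    elif g.shape[1] != 3:
        raise ValueError("bvec file must be 3 rows x N columns")
    if g.shape[0] != b.size:
        raise ValueError(
            f"bval count ({b.size}) does not match bvec count ({g.shape[0]})"
        )
    if np.max(b) > B_UNIT_THRESHOLD:
        log.info("bvals appear to be in s/mm^2 (max %.0f); converting to ms/um^2", b.max())
        b = b / 1000.0
    else:
        log.info("bvals interpreted as ms/um^2 (max %.3f)", float(np.max(b, initial=0)))
    nrm = np.linalg.norm(g, axis=1)
    dw = b > 0
    if np.any(nrm[dw] == 0):
        raise ValueError("zero bvec for a volume with b > 0")
    off = np.abs(nrm[dw] - 1.0) > 1e-3
    if np.any(off):
        warnings.warn(f"renormalizing {int(off.sum())} non-unit bvecs")
    g = g.copy()
    g[dw] = g[dw] / nrm[dw, None]
    return b, g


def write_bvals_bvecs(bval_path: str, bvec_path: str, b: np.ndarray, g: np.ndarray) -> None:
    np.savetxt(bval_path, np.asarray(b)[None, :], fmt="%.6g")
    np.savetxt(bvec_path, np.asarray(g).T, fmt="%.8f")


def _affine_rotation(affine: np.ndarray) -> np.ndarray:
    A = np.asarray(affine, dtype=float)[:3, :3]
    return A / np.linalg.norm(A, axis=0, keepdims=True)


def read_dwi(
    nifti_path: str, bval_path: str, bvec_path: str, frame: str = "image"
) -> tuple[np.ndarray, NominalProtocol, np.ndarray]:
    """Load a 4-D DWI: (data, nominal protocol in scanner frame, affine)."""
    img = nib.load(nifti_path)
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError("DWI must be a 4-D volume")
    affine = img.affine
    if not np.all(np.isfinite(affine)):
        raise ValueError("unreadable affine")
    b, g = read_bvals_bvecs(bval_path, bvec_path)
    if b.size != data.shape[3]:
        raise ValueError(
            f"volume count ({data.shape[3]}) does not match bvals ({b.size})"
        )
    if frame == "image":
        g = g @ _affine_rotation(affine).T
    elif frame != "scanner":
        raise ValueError("frame must be 'image' or 'scanner'")
    return data, NominalProtocol(b, g), affine


def write_dwi(
    out_dir: str,
    data: np.ndarray,
    protocol: NominalProtocol,
    affine: np.ndarray,
    stem: str = "dwi",
) -> dict[str, str]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "nifti": str(out / f"{stem}.nii"),
        "bval": str(out / f"{stem}.bval"),
        "bvec": str(out / f"{stem}.bvec"),
    }
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine), paths["nifti"])
    # directions written back in image coordinates (FSL dialect)
    g_img = protocol.g @ np.linalg.inv(_affine_rotation(affine)).T
    write_bvals_bvecs(paths["bval"], paths["bvec"], protocol.b, g_img)
    return paths


def read_lfield(path: str) -> GradientCoilTensorField:
    """9-component 4-D NIfTI -> coil tensor field (row-major components)."""
    img = nib.load(path)
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4 or data.shape[3] != 9:
        raise ValueError(
            f"L-field NIfTI must have 9 components, got shape {data.shape}"
        )
    grid = VoxelGrid(data.shape[:3], img.affine)
    return GradientCoilTensorField(grid, data.reshape(*data.shape[:3], 3, 3))


def write_lfield(path: str, field: GradientCoilTensorField) -> None:
    data = field.L.reshape(*field.grid.shape, 9).astype(np.float32)
    nib.save(nib.Nifti1Image(data, field.grid.affine), path)


def read_coilmodel(path: str) -> CoilHarmonicModel:
    with open(path) as fh:
        return CoilHarmonicModel.from_dict(json.load(fh))


def write_coilmodel(path: str, model: CoilHarmonicModel) -> None:
    with open(path, "w") as fh:
        json.dump(model.to_dict(), fh, indent=2)


def write_map(path: str, data: np.ndarray, affine: np.ndarray) -> None:
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine), path)


def write_provenance(path: str, **blocks) -> None:
    """Serialize run provenance (config, seeds, artifact ids) as JSON."""

    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer, np.floating)):
            return o.item()
        if isinstance(o, Path):
            return str(o)
        return str(o)

    with open(path, "w") as fh:
        json.dump(blocks, fh, indent=2, default=default)
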