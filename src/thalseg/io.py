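"""NIfTI reading/writing and run manifests."""

from __future__ import annotations

import hashlib
import json
import platform
from pathlib import Path

import nibabel as nib
import numpy as np

from .types import ScalarVolume, UsageError, check_sparse_labels

__all__ = [
    "read_volume",
    "read_labels",
    "write_volume",
    "write_labels",
    "write_multi_ti",
    "write_manifest",
]


def _load(path):
    path = Path(path)
    if not path.exists():
        raise UsageError(f"no such file: {path}")
    return nib.load(str(path))


def read_volume(path, allow_4d: bool = False):
    """Read a NIfTI volume; returns ``(ScalarVolume or 4D array, affine)``.

    Rejects NaN voxels and non-3D payloads (unless ``allow_4d`` for the
    multi-TI stack).
    """
    img = _load(path)
    data = np.asarray(img.get_fdata(), dtype=np.float64)
    if np.isnan(data).any():
        raise UsageError(f"{path}: volume contains NaN voxels")
    if data.ndim == 4 and allow_4d:
        return data, img.affine
    if data.ndim != 3:
        raise UsageError(
            f"{path}: expected a 3D volume, got {data.ndim}D payload"
        )
    zooms = img.header.get_zooms()[:3]
    return ScalarVolume(data, spacing=tuple(float(z) for z in zooms)), img.affine


def read_labels(path):
    """Read an integer label NIfTI; float payloads with integral values cast."""
    img = _load(path)
    data = np.asarray(img.get_fdata())
    if data.ndim != 3:
        raise UsageError(f"{path}: expected a 3D label volume")
    if np.isnan(data).any():
        raise UsageError(f"{path}: label volume contains NaN voxels")
    if not np.all(data == np.round(data)):
        raise UsageError(f"{path}: label volume contains non-integral values")
    return check_sparse_labels(data.astype(np.int16)), img.affine


def write_volume(vol, path, affine=None) -> None:
    """Write a volume (ScalarVolume or ndarray) with the given affine."""
    values = vol.values if isinstance(vol, ScalarVolume) else np.asarray(vol)
    affine = np.eye(4) if affine is None else affine
    nib.save(nib.Nifti1Image(values.astype(np.float32), affine), str(path))


def write_labels(labels, path, affine=None) -> None:
    """Write a label map as an integer-typed NIfTI."""
    labels = check_sparse_labels(labels)
    affine = np.eye(4) if affine is None else affine
    nib.save(nib.Nifti1Image(labels.astype(np.int16), affine), str(path))


def write_multi_ti(stack, ti_grid, out_dir, affine=None, as_4d: bool = False):
    """Write a multi-TI stack: one 4D NIfTI or per-TI files named by TI (ms)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    affine = np.eye(4) if affine is None else affine
    if as_4d:
        data = np.stack([v.values for v in stack], axis=-1).astype(np.float32)
        path = out_dir / "multi_ti.nii.gz"
        nib.save(nib.Nifti1Image(data, affine), str(path))
        return [path]
    paths = []
    for ti, vol in zip(ti_grid, stack):
        path = out_dir / f"ti_{int(round(ti)):04d}ms.nii.gz"
        write_volume(vol, path, affine)
        paths.append(path)
    return paths


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(out_dir, command: str, config: dict, inputs=()) -> Path:
    """Write a machine-readable run manifest (config, versions, input hashes)."""
    import thalseg

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "command": command,
        "config": config,
        "versions": {
            "thalseg": thalseg.__version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
            "nibabel": nib.__version__,
        },
        "inputs": {str(p): _sha256(p) for p in inputs},
    }
    path = out_dir / "run_manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=str))
    return path
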