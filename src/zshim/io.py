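"""NIfTI / JSON / YAML I/O helpers.

All volumes use NIfTI-1 via nibabel; echo series store echoes on the 4th
dimension.  Gradients in user-facing files are µT/m; internal computation
is SI.  The slice axis is taken from the affine's dominant z direction
unless overridden.
"""

from __future__ import annotations

import json
import pathlib

import nibabel as nib
import numpy as np
import yaml


def save_nifti(path, data: np.ndarray, voxel_size=(1e-3, 1e-3, 1e-3)) -> None:
    """Write an array as NIfTI-1 with a diagonal affine (voxel size in m,
    stored in mm per the NIfTI convention)."""
    affine = np.diag([voxel_size[0] * 1e3, voxel_size[1] * 1e3,
                      voxel_size[2] * 1e3, 1.0])
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float64), affine)
    nib.save(img, str(path))


def load_nifti(path) -> tuple[np.ndarray, tuple]:
    """Read a NIfTI file; returns (data, voxel_size in m)."""
    img = nib.load(str(path))
    zooms = img.header.get_zooms()[:3]
    return np.asarray(img.dataobj, dtype=np.float64), tuple(z * 1e-3 for z in zooms)


def slice_axis_from_affine(path) -> int:
    """Array axis whose direction cosine is dominated by scanner z."""
    img = nib.load(str(path))
    rot = img.affine[:3, :3]
    return int(np.argmax(np.abs(rot[2, :])))


def write_json(path, payload: dict) -> None:
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=_jsonable)


def read_json(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def read_config(path) -> dict:
    """Read a JSON or YAML run configuration."""
    path = pathlib.Path(path)
    with open(path) as fh:
        if path.suffix in (".yml", ".yaml"):
            return yaml.safe_load(fh)
        return json.load(fh)


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    raise TypeError(f"not JSON-serializable: {type(obj)}")
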