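"""Reading and writing volumes (NIfTI via nibabel) with JSON sidecars."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from mocospect.grid import Grid


def save_volume(path, values: np.ndarray, grid: Grid, sidecar: dict | None = None):
    """Write a 3D volume as NIfTI; optional provenance JSON next to it."""
    path = Path(path)
    affine = np.diag(list(grid.spacing) + [1.0])
    affine[:3, 3] = grid.origin
    img = nib.Nifti1Image(np.asarray(values, dtype=np.float32), affine)
    nib.save(img, str(path))
    if sidecar is not None:
        path.with_suffix("").with_suffix(".json").write_text(
            json.dumps(sidecar, indent=2, default=_jsonable)
        )


def load_volume(path) -> tuple[np.ndarray, Grid]:
    img = nib.load(str(path))
    values = np.asarray(img.dataobj, dtype=np.float64)
    affine = img.affine
    spacing = tuple(float(abs(affine[i, i])) for i in range(3))
    origin = tuple(float(affine[i, 3]) for i in range(3))
    return values, Grid(values.shape, spacing, origin)


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return str(obj)


def save_json(path, obj):
    Path(path).write_text(json.dumps(obj, indent=2, default=_jsonable))
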