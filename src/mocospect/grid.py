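"""Voxel grid geometry shared by all volumetric data.

Axis convention (documented, used everywhere): axis 0 = LR (x), axis 1 = AP
(y), axis 2 = CC (z, cranial positive).  Coordinates are in mm relative to
the grid center.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

AXIS_LR, AXIS_AP, AXIS_CC = 0, 1, 2


@dataclass(frozen=True)
class Grid:
    """Regular voxel grid: shape in voxels, isotropic-or-not spacing in mm."""

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = field(default=None)  # mm of voxel (0,0,0)

    def __post_init__(self):
        shape = tuple(int(s) for s in self.shape)
        spacing = tuple(float(s) for s in self.spacing)
        if len(shape) != 3 or len(spacing) != 3:
            raise ValueError("grid must be 3D")
        if any(s <= 0 for s in shape) or any(d <= 0 for d in spacing):
            raise ValueError("shape and spacing must be positive")
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "spacing", spacing)
        if self.origin is None:
            origin = tuple(-(n - 1) / 2.0 * d for n, d in zip(shape, spacing))
            object.__setattr__(self, "origin", origin)
        else:
            object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def voxel_volume_ml(self) -> float:
        return self.voxel_volume_mm3 / 1000.0

    def coords(self):
        """Meshgrid of physical voxel-center coordinates (mm), shape (3, *shape)."""
        axes = [
            self.origin[a] + np.arange(self.shape[a]) * self.spacing[a]
            for a in range(3)
        ]
        return np.meshgrid(*axes, indexing="ij")

    def index_to_mm(self, idx):
        idx = np.asarray(idx, dtype=float)
        return idx * np.asarray(self.spacing) + np.asarray(self.origin)

    def mm_to_index(self, mm):
        mm = np.asarray(mm, dtype=float)
        return (mm - np.asarray(self.origin)) / np.asarray(self.spacing)

    def same_geometry(self, other: "Grid") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing)
            and np.allclose(self.origin, other.origin)
        )


def require_same_geometry(*grids: Grid) -> None:
    first = grids[0]
    for g in grids[1:]:
        if not first.same_geometry(g):
            raise ValueError(f"geometry mismatch: {first} vs {g}")
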