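"""Construction of the seven planning VOIs by thresholding and set algebra.

Masks: liver, lungs, tumors (union + per-lesion), perfused liver (PL),
healthy liver (HL = liver - tumors), healthy perfused liver
(HPL = PL - tumors) and hepatic reserve (HR = liver - PL - tumors).
Liver/lung overlap voxels are assigned to the liver before any derived
mask is computed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

PL_THRESHOLD_FRACTION = 0.05  # of the maximum count inside the liver


@dataclass
class VOISet:
    liver: np.ndarray
    lungs: np.ndarray
    tumor: np.ndarray  # union of lesions
    lesions: list = field(default_factory=list)  # per-lesion masks
    pl: np.ndarray = None
    hl: np.ndarray = None
    hpl: np.ndarray = None
    hr: np.ndarray = None

    def masks(self) -> dict:
        return {
            "liver": self.liver,
            "lungs": self.lungs,
            "tumor": self.tumor,
            "PL": self.pl,
            "HL": self.hl,
            "HPL": self.hpl,
            "HR": self.hr,
        }

    def check_invariants(self) -> None:
        assert not np.any(self.liver & self.lungs), "liver/lung overlap unresolved"
        assert np.array_equal(self.hl, self.liver & ~self.tumor)
        assert np.array_equal(self.hpl, self.pl & ~self.tumor)
        assert np.array_equal(self.hr, self.liver & ~self.pl & ~self.tumor)
        assert not np.any(self.pl & ~self.liver), "PL not within liver"


def resolve_liver_lung_overlap(
    liver: np.ndarray, lungs: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Overlap voxels go to the liver and are removed from the lungs."""
    liver = liver.astype(bool)
    return liver.copy(), lungs.astype(bool) & ~liver


def perfused_liver(
    recon_values: np.ndarray,
    liver: np.ndarray,
    fraction: float = PL_THRESHOLD_FRACTION,
) -> np.ndarray:
    """PL = liver voxels with counts >= fraction * max(counts inside liver)."""
    liver = liver.astype(bool)
    if recon_values.shape != liver.shape:
        raise ValueError("reconstruction and liver mask must share geometry")
    if not liver.any():
        raise ValueError("empty liver mask")
    vmax = float(recon_values[liver].max())
    return (recon_values >= fraction * vmax) & liver


def derive_vois(
    liver: np.ndarray,
    lungs: np.ndarray,
    lesions: list[np.ndarray],
    pl: np.ndarray,
) -> VOISet:
    """Apply the overlap rule and the set-algebra definitions exactly."""
    liver, lungs = resolve_liver_lung_overlap(liver, lungs)
    lesions = [m.astype(bool) for m in lesions]
    tumor = np.zeros_like(liver) if not lesions else np.logical_or.reduce(lesions)
    if np.any(tumor & ~liver):
        warnings.warn("tumor voxels outside the liver; kept in the tumor mask")
    pl = pl.astype(bool) & liver
    vs = VOISet(
        liver=liver,
        lungs=lungs,
        tumor=tumor,
        lesions=lesions,
        pl=pl,
        hl=liver & ~tumor,
        hpl=pl & ~tumor,
        hr=liver & ~pl & ~tumor,
    )
    vs.check_invariants()
    return vs


def voi_summary(vois: VOISet, voxel_volume_ml: float) -> list[dict]:
    rows = []
    for name, mask in vois.masks().items():
        rows.append(
            {"voi": name, "voxels": int(mask.sum()), "ml": float(mask.sum()) * voxel_volume_ml}
        )
    return rows
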