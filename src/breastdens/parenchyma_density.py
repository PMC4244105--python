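"""Parenchyma extraction and breast-density volumetry.

The refined solid breast mask B and the bright-tissue (fat) segmentation S
from the level-set step partition the breast exactly: fat-in-breast is
``S ∧ B`` and the fibroglandular (parenchymal) region is its complement
inside the breast, ``P = B ∧ ¬(S ∧ B)``.  Volumes are voxel counts converted
to liters through the voxel volume; percent density is ``100 · PV / BV``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .volume_io import BinaryMask

__all__ = ["DensityReport", "mask_segmentation", "extract_parenchyma", "compute_report"]


@dataclass
class DensityReport:
    """Breast (BV) and parenchymal (PV) volumes with per-slice provenance."""

    bv_voxels: int
    pv_voxels: int
    bv_liters: float
    pv_liters: float
    density_percent: float
    per_slice: pd.DataFrame  # columns: z, bv_vox, pv_vox

    def to_dict(self) -> dict:
        return {
            "bv_voxels": self.bv_voxels,
            "pv_voxels": self.pv_voxels,
            "bv_liters": self.bv_liters,
            "pv_liters": self.pv_liters,
            "density_percent": self.density_percent,
            "per_slice": self.per_slice.to_dict(orient="list"),
        }


def _check_shapes(a: BinaryMask, b: BinaryMask) -> None:
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")


def mask_segmentation(seg3d: BinaryMask, breast: BinaryMask) -> BinaryMask:
    """Restrict the segmentation to the breast mask (elementwise AND)."""
    _check_shapes(seg3d, breast)
    return BinaryMask(data=(seg3d.data & breast.data), spacing=breast.spacing)


def extract_parenchyma(seg3d: BinaryMask, breast: BinaryMask) -> BinaryMask:
    """Fibroglandular region: breast voxels not classified as bright fat.

    ``P = B ∧ ¬(S ∧ B)``, so P and the masked segmentation partition the
    breast mask exactly.
    """
    _check_shapes(seg3d, breast)
    fat_in_breast = seg3d.data & breast.data
    return BinaryMask(data=(breast.data & (1 - fat_in_breast)), spacing=breast.spacing)


def compute_report(breast: BinaryMask, parenchyma: BinaryMask,
                   spacing: tuple[float, float, float] | None = None) -> DensityReport:
    """BV/PV voxel counts, liters and percent density with a per-slice table."""
    _check_shapes(breast, parenchyma)
    if np.any(parenchyma.data & (1 - breast.data)):
        raise ValueError("parenchyma mask extends outside the breast mask")
    spacing = spacing or breast.spacing
    bv = breast.count()
    pv = parenchyma.count()
    if bv == 0:
        raise ValueError("empty breast mask: density undefined")
    voxel_mm3 = float(np.prod(spacing))
    per_slice = pd.DataFrame(
        {
            "z": np.arange(breast.shape[0]),
            "bv_vox": breast.data.sum(axis=(1, 2)).astype(int),
            "pv_vox": parenchyma.data.sum(axis=(1, 2)).astype(int),
        }
    )
    return DensityReport(
        bv_voxels=bv,
        pv_voxels=pv,
        bv_liters=bv * voxel_mm3 * 1e-6,
        pv_liters=pv * voxel_mm3 * 1e-6,
        density_percent=100.0 * pv / bv,
        per_slice=per_slice,
    )
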