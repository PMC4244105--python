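"""Volume and mask I/O with explicit voxel spacing.

All downstream modules consume the container types defined here.  Arrays are
indexed ``(z, y, x)`` with ``z`` the axial slice index, ``y`` increasing
anterior → posterior (``y = 0`` is the nipple-side row) and ``x`` left–right.
Spacing is stored as ``(dz, dy, dx)`` in millimetres.

Supported on disk: NIfTI-1 (read/write, via nibabel) and DICOM series
directories (read only, via SimpleITK).  Masks are written as NIfTI with a
uint8 {0, 1} payload.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "ImageVolume",
    "BinaryMask",
    "SliceIndexRange",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "crop_slices",
]


class VolumeFormatError(ValueError):
    """Raised for unreadable or internally inconsistent volume files."""


@dataclass
class ImageVolume:
    """A 3D scalar intensity grid with voxel spacing and axial orientation.

    Parameters
    ----------
    data : ndarray, shape (nz, ny, nx)
        Non-negative, finite intensities.
    spacing : tuple of float
        ``(dz, dy, dx)`` in mm, strictly positive.
    origin : tuple of float
        Position of voxel (0, 0, 0) in mm.
    orientation_tag : str
        Fixed at ``"axial"``: y runs anterior → posterior, z is the slice index.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    orientation_tag: str = "axial"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise ValueError(f"volume must be 3D with all dimensions >= 1, got shape {self.data.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three strictly positive values, got {self.spacing}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume intensities must be finite")
        if self.data.min() < 0:
            raise ValueError("volume intensities must be non-negative")
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_slices(self) -> int:
        return self.data.shape[0]

    @property
    def voxel_volume_mm3(self) -> float:
        dz, dy, dx = self.spacing
        return dz * dy * dx


@dataclass
class BinaryMask:
    """A 3D {0, 1} grid sharing the spacing convention of :class:`ImageVolume`."""

    data: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim != 3:
            raise ValueError(f"mask must be 3D, got shape {arr.shape}")
        vals = np.unique(arr)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError("mask values must be 0 or 1")
        self.data = arr.astype(np.uint8)
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three strictly positive values, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def count(self) -> int:
        """Number of foreground voxels."""
        return int(self.data.sum())


@dataclass(frozen=True)
class SliceIndexRange:
    """Inclusive user-selected [z_start, z_end] slice range."""

    z_start: int
    z_end: int

    def __post_init__(self) -> None:
        if self.z_start < 0 or self.z_end < self.z_start:
            raise ValueError(f"invalid slice range ({self.z_start}, {self.z_end})")

    def validate(self, n_slices: int) -> None:
        if self.z_end >= n_slices:
            raise ValueError(f"slice range ({self.z_start}, {self.z_end}) exceeds {n_slices} slices")

    def __len__(self) -> int:
        return self.z_end - self.z_start + 1

    def slices(self) -> range:
        return range(self.z_start, self.z_end + 1)


def _affine(spacing: tuple[float, float, float], origin: tuple[float, float, float]) -> np.ndarray:
    # nibabel stores (x, y, z); build a diagonal affine from (dz, dy, dx)
    dz, dy, dx = spacing
    aff = np.diag([dx, dy, dz, 1.0])
    aff[:3, 3] = origin[::-1]
    return aff


def write_volume(vol: ImageVolume, path: str | os.PathLike) -> None:
    """Write a volume as NIfTI-1; array stored (x, y, z) per NIfTI convention."""
    img = nib.Nifti1Image(np.asarray(vol.data).T, _affine(vol.spacing, vol.origin))
    img.header.set_zooms((vol.spacing[2], vol.spacing[1], vol.spacing[0]))
    nib.save(img, str(path))


def write_mask(mask: BinaryMask, path: str | os.PathLike) -> None:
    """Write a binary mask as NIfTI-1 with uint8 payload."""
    img = nib.Nifti1Image(mask.data.T.astype(np.uint8), _affine(mask.spacing, (0.0, 0.0, 0.0)))
    img.header.set_zooms((mask.spacing[2], mask.spacing[1], mask.spacing[0]))
    nib.save(img, str(path))


def _read_nifti(path: Path) -> ImageVolume:
    try:
        img = nib.load(str(path))
    except Exception as exc:  # pragma: no cover - nibabel error text varies
        raise VolumeFormatError(f"cannot read NIfTI file {path}: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise VolumeFormatError(f"{path}: expected a 3D NIfTI volume, got shape {data.shape}")
    zx, zy, zz = img.header.get_zooms()[:3]
    origin = tuple(float(v) for v in img.affine[:3, 3][::-1])
    return ImageVolume(data=data.T, spacing=(float(zz), float(zy), float(zx)), origin=origin)


def _read_dicom_series(path: Path) -> ImageVolume:
    import SimpleITK as sitk

    reader = sitk.ImageSeriesReader()
    names = reader.GetGDCMSeriesFileNames(str(path))
    if not names:
        raise IOError(f"no DICOM series found in directory {path}")
    reader.SetFileNames(names)
    try:
        img = reader.Execute()
    except Exception as exc:
        raise VolumeFormatError(f"cannot read DICOM series in {path}: {exc}") from exc
    sx, sy, sz = img.GetSpacing()
    # verify slice positions are evenly spaced: SimpleITK fills sz from positions,
    # but a series with irregular gaps must be rejected rather than silently resampled
    origins = [float(sitk.ReadImage(str(n)).GetOrigin()[2]) for n in names]
    if len(origins) > 2:
        gaps = np.diff(sorted(origins))
        if gaps.size and (gaps.max() - gaps.min()) > 1e-3 * max(abs(gaps.mean()), 1.0):
            raise VolumeFormatError(f"inconsistent slice spacing in DICOM series {path}")
    data = sitk.GetArrayFromImage(img)  # (z, y, x) already
    origin = img.GetOrigin()
    return ImageVolume(
        data=data,
        spacing=(float(sz), float(sy), float(sx)),
        origin=(float(origin[2]), float(origin[1]), float(origin[0])),
    )


def read_volume(path: str | os.PathLike, format_hint: str | None = None) -> ImageVolume:
    """Read a 3D volume from a NIfTI file or a DICOM series directory.

    Parameters
    ----------
    path : path-like
        A ``.nii``/``.nii.gz`` file or a directory containing one DICOM series.
    format_hint : {"nifti", "dicom", None}
        Force a reader; by default inferred from the path (directory → DICOM).
    """
    p = Path(path)
    if not p.exists():
        raise IOError(f"no such file or directory: {p}")
    hint = format_hint
    if hint is None:
        hint = "dicom" if p.is_dir() else "nifti"
    if hint == "dicom":
        return _read_dicom_series(p)
    if hint == "nifti":
        return _read_nifti(p)
    raise ValueError(f"unknown format hint {hint!r}")


def read_mask(path: str | os.PathLike, spacing: tuple[float, float, float] | None = None) -> BinaryMask:
    """Read a binary mask from NIfTI; nonzero voxels become 1."""
    vol = _read_nifti(Path(path))
    return BinaryMask(data=(vol.data > 0).astype(np.uint8), spacing=spacing or vol.spacing)


def crop_slices(vol: ImageVolume, r: SliceIndexRange) -> ImageVolume:
    """Restrict a volume to the user-selected inclusive slice range."""
    r.validate(vol.n_slices)
    dz = vol.spacing[0]
    origin = (vol.origin[0] + r.z_start * dz, vol.origin[1], vol.origin[2])
    return ImageVolume(
        data=vol.data[r.z_start : r.z_end + 1].copy(),
        spacing=vol.spacing,
        origin=origin,
        orientation_tag=vol.orientation_tag,
    )
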