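"""Synthetic prone-breast MR phantoms with known ground truth.

The generator emulates an axial, T1-weighted, non-fat-suppressed prone breast
acquisition: two pendant half-ellipsoidal breasts of bright fatty tissue with
sparse darker internal parenchyma, a darker posterior body/pectoral band, dark
air background, subcutaneous fat along the posterior body wall, a smooth
multiplicative bias field (anterior→posterior coil falloff plus a left–right
B1 modulation) and additive zero-mean Gaussian noise.  The observed volume is

    U = J * b + n,   clipped at zero,

where ``J`` is the piecewise-constant tissue image, ``b`` the strictly
positive bias field (normalized to mean 1) and ``n`` the noise realization.

Every phantom carries its exact ground truth (breast mask, parenchyma mask,
bias field, clean image), standing in for the manual reference segmentations
used to validate the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import ndimage as ndi

from .volume_io import BinaryMask, ImageVolume

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "generate_phantom",
    "bias_profile",
    "make_leakage_fixture",
]


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of a synthetic prone-breast phantom.

    Intensities follow the T1 non-fat-suppressed contrast ordering
    ``air < body ≈ parenchyma < fat``.  ``bias_ap_strength`` scales the
    anterior→posterior logistic falloff, ``bias_lr_strength`` the left–right
    cosine modulation; ``noise_sd`` is the Gaussian noise standard deviation
    in intensity units (default 2% of the fat intensity).
    """

    shape: tuple[int, int, int] = (40, 128, 128)
    spacing: tuple[float, float, float] = (2.0, 1.0, 1.0)
    fat_intensity: float = 400.0
    parenchyma_intensity: float = 150.0
    body_intensity: float = 130.0
    air_intensity: float = 20.0
    target_density_fraction: float = 0.20
    bias_ap_strength: float = 0.8
    bias_lr_strength: float = 0.1
    noise_sd: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or min(self.shape) < 8:
            raise ValueError(f"shape must be 3D with all dims >= 8, got {self.shape}")
        if not (0.0 <= self.air_intensity < self.parenchyma_intensity < self.fat_intensity):
            raise ValueError("intensity ordering air < parenchyma < fat violated")
        if self.body_intensity < 0:
            raise ValueError("body intensity must be non-negative")
        if not 0.0 < self.target_density_fraction < 1.0:
            raise ValueError("target_density_fraction must lie in (0, 1)")
        if self.bias_ap_strength < 0 or self.bias_lr_strength < 0:
            raise ValueError("bias strengths must be non-negative")
        if self.bias_lr_strength >= 1.0:
            raise ValueError("bias_lr_strength must be < 1 to keep the field positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass
class PhantomTruth:
    """A generated phantom together with its exact ground truth."""

    volume: ImageVolume
    breast_mask: BinaryMask
    parenchyma_mask: BinaryMask
    bias_field: np.ndarray
    clean_image: np.ndarray
    fat_mask: BinaryMask  # every bright (fatty) voxel, incl. subcutaneous fat
    chest_wall_y: int  # posterior extent of the breasts / anterior body surface
    spec: PhantomSpec
    lobe_mask: BinaryMask | None = None  # injected leakage voxels, if any
    bridge_mask: BinaryMask | None = None  # single-slice lateral fat bridges


def _ellipsoid(shape: tuple[int, int, int], center: tuple[float, float, float],
               semi: tuple[float, float, float]) -> np.ndarray:
    nz, ny, nx = shape
    z, y, x = np.ogrid[:nz, :ny, :nx]
    cz, cy, cx = center
    az, ay, ax = semi
    return ((z - cz) / az) ** 2 + ((y - cy) / ay) ** 2 + ((x - cx) / ax) ** 2 <= 1.0


def _bias_field(spec: PhantomSpec) -> np.ndarray:
    nz, ny, nx = spec.shape
    y = np.arange(ny, dtype=float)
    x = np.arange(nx, dtype=float)
    # logistic coil falloff: bright near the nipples (small y), dark near the chest
    g = 1.0 / (1.0 + np.exp((y - 0.45 * ny) / (0.18 * ny)))
    by = 1.0 + spec.bias_ap_strength * g
    bx = 1.0 + spec.bias_lr_strength * np.cos(2.0 * np.pi * x / max(nx - 1, 1))
    field2d = np.outer(by, bx)
    field = np.broadcast_to(field2d, (nz, ny, nx)).copy()
    field /= field.mean()
    return field


def _breast_geometry(spec: PhantomSpec):
    """Masks of the deterministic anatomy (everything except parenchyma)."""
    nz, ny, nx = spec.shape
    y_chest = int(round(0.75 * ny))
    cz = (nz - 1) / 2.0
    az = 0.42 * nz
    ay = 0.62 * ny
    ax = 0.24 * nx
    cxs = (0.30 * nx, 0.70 * nx)

    breasts = np.zeros(spec.shape, dtype=bool)
    for cx in cxs:
        breasts |= _ellipsoid(spec.shape, (cz, y_chest, cx), (az, ay, ax))
    breasts[:, y_chest + 1 :, :] = False  # pendant half: nothing posterior to the chest wall

    body = np.zeros(spec.shape, dtype=bool)
    body[:, y_chest:, :] = True

    # posterior subcutaneous fat layer along the back
    shell = np.zeros(spec.shape, dtype=bool)
    shell[:, ny - 5 :, :] = True

    # inframammary fat patches under each breast, clear of the midline
    z_lo = max(int(np.floor(cz - az)) + 1, 0)
    z_hi = min(int(np.ceil(cz + az)), nz)
    mid_lo, mid_hi = nx // 2 - 12, nx // 2 + 12
    patches = np.zeros(spec.shape, dtype=bool)
    for cx in cxs:
        x_lo = max(int(cx - ax), 2)
        x_hi = min(int(cx + ax) + 1, nx - 2)
        patches[z_lo:z_hi, y_chest : y_chest + 3, x_lo:x_hi] = True
    patches[:, :, mid_lo:mid_hi] = False

    # two single-slice lateral fat bridges tie the patches to the posterior
    # shell (continuity of the subcutaneous fat sheet); kept off most slices so
    # the pectoral band is never enclosed in-plane
    bridges = np.zeros(spec.shape, dtype=bool)
    z_a = z_lo + (z_hi - z_lo) // 3
    z_b = z_lo + 2 * (z_hi - z_lo) // 3
    bridges[z_a, y_chest:, 0:2] = True
    bridges[z_a, y_chest : y_chest + 3, 0 : int(cxs[0])] = True
    bridges[z_b, y_chest:, nx - 2 : nx] = True
    bridges[z_b, y_chest : y_chest + 3, int(cxs[1]) : nx] = True

    fat_accessories = shell | patches | bridges
    return breasts, body, fat_accessories, bridges, y_chest, (cz, az, ay, ax, cxs)


def _parenchyma_mask(spec: PhantomSpec, breasts: np.ndarray, geom, rng: np.random.Generator) -> np.ndarray:
    """Blobby medial parenchyma occupying ~target fraction of the breast volume."""
    cz, az, ay, ax, cxs = geom
    nz, ny, nx = spec.shape
    y_chest = int(round(0.75 * ny))

    allowed = np.zeros(spec.shape, dtype=bool)
    for cx in cxs:
        allowed |= _ellipsoid(spec.shape, (cz, y_chest - 0.12 * ay, cx), (0.72 * az, 0.72 * ay, 0.72 * ax))
    allowed &= breasts
    allowed[:, y_chest - 3 :, :] = False  # keep a fat margin at the chest wall

    n_breast = int(breasts.sum())
    needed = spec.target_density_fraction * n_breast
    n_allowed = int(allowed.sum())
    if n_allowed == 0 or needed > 0.95 * n_allowed:
        raise ValueError(
            f"target density fraction {spec.target_density_fraction} not achievable: "
            f"needs {needed:.0f} voxels but only {n_allowed} are available inside the breasts"
        )

    field = rng.standard_normal(spec.shape)
    # isotropic 4 mm correlation length, converted to voxels per axis
    sig = tuple(4.0 / s for s in spec.spacing)
    field = ndi.gaussian_filter(field, sigma=sig)

    vals = field[allowed]
    # bisection on the occupancy quantile so the post-closing voxel count hits target
    lo, hi = 0.0, 1.0
    struct = ndi.generate_binary_structure(3, 1)
    mask = np.zeros(spec.shape, dtype=bool)
    for _ in range(30):
        frac = 0.5 * (lo + hi)
        thr = np.quantile(vals, 1.0 - min(frac, 1.0 - 1e-9))
        cand = allowed & (field > thr)
        cand = ndi.binary_closing(cand, structure=struct, iterations=1) & allowed
        got = cand.sum() / n_breast
        mask = cand
        if abs(got - spec.target_density_fraction) < 0.003:
            break
        if got < spec.target_density_fraction:
            lo = frac
        else:
            hi = frac
    return mask


def generate_phantom(spec: PhantomSpec) -> PhantomTruth:
    """Generate a synthetic prone-breast phantom with full ground truth.

    Deterministic given ``spec.seed``: all randomness (parenchyma texture,
    noise realization) flows from one :class:`numpy.random.Generator`.
    """
    rng = np.random.default_rng(spec.seed)
    breasts, body, fat_acc, bridges, y_chest, geom = _breast_geometry(spec)
    parenchyma = _parenchyma_mask(spec, breasts, geom, rng)

    fat = (breasts & ~parenchyma) | fat_acc
    clean = np.full(spec.shape, spec.air_intensity, dtype=float)
    clean[body] = spec.body_intensity
    clean[fat] = spec.fat_intensity
    clean[parenchyma] = spec.parenchyma_intensity

    bias = _bias_field(spec)
    noise = rng.normal(0.0, spec.noise_sd, spec.shape) if spec.noise_sd > 0 else 0.0
    observed = np.clip(clean * bias + noise, 0.0, None)

    return PhantomTruth(
        volume=ImageVolume(data=observed, spacing=spec.spacing),
        breast_mask=BinaryMask(data=breasts.astype(np.uint8), spacing=spec.spacing),
        parenchyma_mask=BinaryMask(data=parenchyma.astype(np.uint8), spacing=spec.spacing),
        bias_field=bias,
        clean_image=clean,
        fat_mask=BinaryMask(data=fat.astype(np.uint8), spacing=spec.spacing),
        chest_wall_y=y_chest,
        spec=spec,
        bridge_mask=BinaryMask(data=bridges.astype(np.uint8), spacing=spec.spacing),
    )


def bias_profile(field: np.ndarray, line: tuple[tuple[int, int, int], tuple[int, int, int]]) -> np.ndarray:
    """Sample a bias field along a straight voxel line (inclusive endpoints).

    ``line`` is a pair of (z, y, x) integer voxel coordinates.  Returns the
    field values at nearest-voxel positions along the segment, mirroring the
    intensity-profile inspection used to characterize coil falloff.
    """
    start = np.asarray(line[0], dtype=float)
    stop = np.asarray(line[1], dtype=float)
    if start.shape != (3,) or stop.shape != (3,):
        raise ValueError("line endpoints must be (z, y, x) triples")
    shape = np.asarray(field.shape)
    for p in (start, stop):
        if np.any(p < 0) or np.any(p > shape - 1):
            raise ValueError(f"line endpoint {tuple(p)} lies outside the grid {field.shape}")
    n = int(np.abs(stop - start).max()) + 1
    if n < 2 and np.all(start == stop):
        raise ValueError("zero-length line")
    idx = np.rint(np.linspace(start, stop, n)).astype(int)
    return field[idx[:, 0], idx[:, 1], idx[:, 2]]


def breast_slice_range(truth: PhantomTruth, min_frac: float = 0.05):
    """User-style processing range: slices with a substantial breast cross-section.

    Mirrors the manual start/end slice selection that excludes slices with
    irrelevant or negligible breast content: a slice is included when its
    breast area is at least ``min_frac`` of the maximal cross-section.
    """
    from .volume_io import SliceIndexRange

    areas = truth.breast_mask.data.sum(axis=(1, 2))
    keep = np.nonzero(areas >= min_frac * areas.max())[0]
    if keep.size == 0:
        raise ValueError("phantom has no breast content")
    return SliceIndexRange(int(keep.min()), int(keep.max()))


def midline_ap_line(truth: PhantomTruth) -> tuple[tuple[int, int, int], tuple[int, int, int]]:
    """Anterior→posterior line through the left breast center on the central slice."""
    nz, ny, nx = truth.spec.shape
    x = int(0.30 * nx)
    z = nz // 2
    return (z, 0, x), (z, ny - 1, x)


def make_leakage_fixture(
    base: PhantomTruth,
    lobe_radius: float = 8.0,
    neck_width: int = 2,
    z_slices: Sequence[int] = (),
) -> PhantomTruth:
    """Inject a fat-bright lobe into the pectoral region on selected slices.

    The returned phantom shows the lobe (and, for ``neck_width > 0``, a thin
    neck connecting it to the breast) at fat intensity, while ``breast_mask``
    remains the uncorrupted truth — emulating step-1 segmentations that leak
    into the pectoral muscle.  ``lobe_mask`` records the injected voxels.
    """
    spec = base.spec
    nz, ny, nx = spec.shape
    z_slices = sorted(set(int(z) for z in z_slices))
    for z in z_slices:
        if not 0 <= z < nz:
            raise ValueError(f"lobe slice {z} outside volume with {nz} slices")
    y_chest = base.chest_wall_y
    cy = y_chest + int(lobe_radius) + 4
    cx = int(0.30 * nx)
    if cy + lobe_radius >= ny - 5 or lobe_radius < 1:
        raise ValueError("lobe cannot be placed posterior to the breast inside the body band")

    lobe = np.zeros(spec.shape, dtype=bool)
    yy, xx = np.ogrid[:ny, :nx]
    disk = (yy - cy) ** 2 + (xx - cx) ** 2 <= lobe_radius**2
    for z in z_slices:
        lobe[z, disk] = True
        if neck_width > 0:
            half = max(neck_width // 2, 0)
            lobe[z, y_chest : cy + 1, cx - half : cx - half + max(neck_width, 1)] = True

    clean = base.clean_image.copy()
    clean[lobe] = spec.fat_intensity
    rng = np.random.default_rng(spec.seed)
    rng.standard_normal(spec.shape)  # consume the parenchyma texture draw → same noise realization
    noise = rng.normal(0.0, spec.noise_sd, spec.shape) if spec.noise_sd > 0 else 0.0
    observed = np.clip(clean * base.bias_field + noise, 0.0, None)

    injected = lobe & ~(base.fat_mask.data.astype(bool))
    return replace(
        base,
        volume=ImageVolume(data=observed, spacing=spec.spacing),
        clean_image=clean,
        fat_mask=BinaryMask(data=(base.fat_mask.data.astype(bool) | lobe).astype(np.uint8), spacing=spec.spacing),
        lobe_mask=BinaryMask(data=injected.astype(np.uint8), spacing=spec.spacing),
    )
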