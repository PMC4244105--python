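"""Geometric refinement of the raw fat segmentation into a solid breast mask.

The bright-tissue segmentation from the level-set step typically contains,
besides the breasts, subcutaneous fat along the body wall and occasional
leakage into the pectoral muscle.  This module turns it into a solid breast
mask by, in order:

1. extracting the largest 26-connected 3D component,
2. finding a reference slice whose breast outline agrees with its neighbours,
3. propagating that outline through the stack, splitting each slice at
   narrow necks with a watershed on the inverted distance transform and
   discarding pieces that do not overlap the already-refined neighbour,
4. filling in-plane holes and excluding the posterior part of the bounding
   box (lung and other irrelevant structures),
5. closing concavities with rolling-ball (morphological closing) kernels
   whose radius depends on the region (nipple/areola, pectoral boundary,
   remaining skin folds),
6. cutting at the sternum: removing everything posterior to the lowest
   breast-tissue point near the midline.

Signed labels use +1 for foreground and -1 for background.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.morphology import h_maxima
from skimage.segmentation import watershed

from .volume_io import BinaryMask

__all__ = [
    "BreastComponent",
    "RefinementParams",
    "extract_largest_component",
    "find_reference_slice",
    "evaluate_components",
    "update_slice",
    "propagate_boundaries",
    "fill_holes_and_exclude_lower",
    "close_concavities",
    "cut_at_sternum",
    "build_breast_mask",
]

logger = logging.getLogger(__name__)

_STRUCT_3D = np.ones((3, 3, 3), dtype=bool)  # 26-connectivity
_STRUCT_2D = np.ones((3, 3), dtype=bool)  # 8-connectivity

FOREGROUND = 1
BACKGROUND = -1


@dataclass
class BreastComponent:
    """A signed-label 3D mask with cached centroid and bounding box.

    ``labels`` holds +1 (foreground) / -1 (background).  ``centroid`` is the
    foreground centre of mass (z_c, y_c, x_c) in voxel coordinates; ``bbox``
    the minimal axis-aligned box as ((z1, y1, x1), (z2, y2, x2)), inclusive.
    """

    labels: np.ndarray
    spacing: tuple[float, float, float]
    centroid: tuple[float, float, float]
    bbox: tuple[tuple[int, int, int], tuple[int, int, int]]

    @classmethod
    def from_foreground(cls, fg: np.ndarray, spacing: tuple[float, float, float]) -> "BreastComponent":
        fg = fg.astype(bool)
        if not fg.any():
            raise ValueError("empty foreground")
        idx = np.nonzero(fg)
        centroid = tuple(float(np.mean(a)) for a in idx)
        bbox = (
            tuple(int(a.min()) for a in idx),
            tuple(int(a.max()) for a in idx),
        )
        labels = np.where(fg, FOREGROUND, BACKGROUND).astype(np.int8)
        return cls(labels=labels, spacing=spacing, centroid=centroid, bbox=bbox)

    @property
    def foreground(self) -> np.ndarray:
        return self.labels == FOREGROUND

    def to_mask(self) -> BinaryMask:
        return BinaryMask(data=self.foreground.astype(np.uint8), spacing=self.spacing)


@dataclass(frozen=True)
class RefinementParams:
    """Tunables of the mask-refinement step (all fractions of the component bbox).

    ``triple_similarity_frac`` is the reference-slice threshold T: a slice
    qualifies when every difference-component against both neighbours is
    smaller than T times the breast area on that slice.  Ball radii are in mm
    and converted to voxels through the volume spacing.
    """

    triple_similarity_frac: float = 0.05
    overlap_frac: float = 0.5
    lower_exclusion_frac: float = 0.85
    nipple_ball_mm: float = 12.0
    pectoral_ball_mm: float = 8.0
    side_ball_mm: float = 3.0
    nipple_band_frac: float = 0.25
    pectoral_band_frac: float = 0.25
    sternum_center_window_frac: float = 0.15

    def __post_init__(self) -> None:
        fracs = (
            self.triple_similarity_frac, self.overlap_frac, self.lower_exclusion_frac,
            self.nipple_band_frac, self.pectoral_band_frac, self.sternum_center_window_frac,
        )
        if any(not 0.0 < f < 1.0 for f in fracs):
            raise ValueError("all fraction parameters must lie in (0, 1)")
        if min(self.nipple_ball_mm, self.pectoral_ball_mm, self.side_ball_mm) <= 0:
            raise ValueError("ball radii must be positive")


def extract_largest_component(seg3d: BinaryMask) -> BreastComponent:
    """Select the biggest 26-connected 3D component of the segmentation.

    Ties are broken deterministically by label order (a warning is logged).
    """
    fg = seg3d.data.astype(bool)
    if not fg.any():
        raise ValueError("empty segmentation: no foreground voxels")
    labels, n = ndi.label(fg, structure=_STRUCT_3D)
    sizes = np.bincount(labels.ravel())[1:]
    best = int(np.argmax(sizes)) + 1
    if (sizes == sizes.max()).sum() > 1:
        logger.warning("largest-component tie (%d voxels); keeping lowest label", sizes.max())
    return BreastComponent.from_foreground(labels == best, seg3d.spacing)


def _difference_component_areas(a: np.ndarray, b: np.ndarray) -> list[int]:
    """Areas of the 8-connected components of the set difference a \\ b."""
    diff = a & ~b
    if not diff.any():
        return []
    lab, n = ndi.label(diff, structure=_STRUCT_2D)
    return np.bincount(lab.ravel())[1:].tolist()


def find_reference_slice(comp: BreastComponent, p: RefinementParams | None = None) -> int:
    """Find a slice whose breast outline agrees with both its neighbours.

    Scans triples (i-1, i, i+1) starting at the component centroid slice and
    moving outward in both directions; slice i qualifies when every connected
    component of the symmetric slice differences is smaller than
    ``T * area(B_i)``.  The search stops at the first qualifying slice.
    Falls back to the centroid slice (with a warning) if none qualifies.
    """
    p = p or RefinementParams()
    fg = comp.foreground
    nonempty = [z for z in range(fg.shape[0]) if fg[z].any()]
    if len(nonempty) < 3:
        raise ValueError("need at least 3 slices with foreground to select a reference")
    z_c = int(round(comp.centroid[0]))
    z_lo, z_hi = nonempty[0] + 1, nonempty[-1] - 1
    z_c = min(max(z_c, z_lo), z_hi)

    order: list[int] = []
    for off in range(0, max(z_c - z_lo, z_hi - z_c) + 1):
        for z in (z_c + off, z_c - off) if off else (z_c,):
            if z_lo <= z <= z_hi and z not in order:
                order.append(z)

    for i in order:
        b_prev, b_i, b_next = fg[i - 1], fg[i], fg[i + 1]
        area = int(b_i.sum())
        if area == 0:
            continue
        areas: list[int] = []
        for nb in (b_prev, b_next):
            areas += _difference_component_areas(b_i, nb)  # positive differences
            areas += _difference_component_areas(nb, b_i)  # negative differences
        if not areas or max(areas) < p.triple_similarity_frac * area:
            return i
    warnings.warn("no qualifying reference slice found; falling back to the centroid slice")
    return z_c


def _watershed_split(slice_mask: np.ndarray) -> np.ndarray:
    """Split a 2D mask at narrow necks: watershed on the inverted distance map.

    Minima are imposed at h-maxima (h = 1 voxel) of the distance transform to
    avoid over-fragmentation.  Returns a label image with 0 on the background
    and on the watershed ridge lines.
    """
    dist = ndi.distance_transform_edt(slice_mask)
    peaks = h_maxima(dist, 1)
    markers, n = ndi.label(peaks, structure=_STRUCT_2D)
    if n == 0:
        markers, n = ndi.label(slice_mask, structure=_STRUCT_2D)
    return watershed(-dist, markers=markers, mask=slice_mask, watershed_line=True)


def evaluate_components(slice_i_mask: np.ndarray, slice_j_mask: np.ndarray,
                        p: RefinementParams | None = None, dilate_vox: int = 0):
    """Split slice j at necks and keep the pieces that overlap slice i.

    Returns ``(kept_masks, ws_labels, kept_label_ids)`` where ``kept_masks``
    is the list of kept 2D boolean components.  A component is kept when
    ``overlap_area / component_area >= overlap_frac`` against the (already
    refined) neighbouring slice i.  ``dilate_vox`` dilates slice i before the
    overlap test: with anisotropic voxels a tissue boundary legitimately
    shifts several in-plane voxels per slice step, and strict voxel overlap
    would under-measure through-plane continuity.
    """
    p = p or RefinementParams()
    slice_i_mask = np.asarray(slice_i_mask).astype(bool)
    slice_j_mask = np.asarray(slice_j_mask).astype(bool)
    if not slice_i_mask.any():
        raise ValueError("reference slice i is empty")
    if not slice_j_mask.any():
        return [], np.zeros_like(slice_j_mask, dtype=np.int32), []
    if dilate_vox > 0:
        slice_i_mask = ndi.binary_dilation(slice_i_mask, structure=_STRUCT_2D, iterations=dilate_vox)
    ws = _watershed_split(slice_j_mask)
    kept: list[np.ndarray] = []
    kept_ids: list[int] = []
    for lab in range(1, int(ws.max()) + 1):
        m = ws == lab
        area = int(m.sum())
        if area == 0:
            continue
        overlap = int((m & slice_i_mask).sum())
        if overlap / area >= p.overlap_frac:
            kept.append(m)
            kept_ids.append(lab)
    return kept, ws, kept_ids


def update_slice(kept_components, shape: tuple[int, int],
                 ws_labels: np.ndarray | None = None,
                 kept_ids=None,
                 original_mask: np.ndarray | None = None) -> np.ndarray:
    """Rebuild a slice from kept components: union plus the watershed ridge
    voxels lying between two kept components; everything else is background.

    ``original_mask`` (the unsplit slice foreground) restricts ridge
    candidates — only in-mask watershed-line voxels separate components.
    Returns signed labels (+1 foreground / -1 background).
    """
    out = np.zeros(shape, dtype=bool)
    for m in kept_components:
        out |= m
    if ws_labels is not None and kept_ids and len(kept_ids) >= 2:
        kept_set = set(int(k) for k in kept_ids)
        ridge = (ws_labels == 0) & ~out
        if original_mask is not None:
            ridge &= np.asarray(original_mask).astype(bool)
        ridge_idx = np.argwhere(ridge)
        ny, nx = shape
        for y, x in ridge_idx:
            neigh = ws_labels[max(y - 1, 0) : y + 2, max(x - 1, 0) : x + 2]
            labs = set(int(v) for v in np.unique(neigh)) - {0}
            if len(labs & kept_set) >= 2:
                out[y, x] = True
    return np.where(out, FOREGROUND, BACKGROUND).astype(np.int8)


def propagate_boundaries(comp: BreastComponent, z_ref: int,
                         p: RefinementParams | None = None) -> BreastComponent:
    """Propagate the reference-slice boundary through the stack.

    Sweeps from ``z_ref`` toward both volume ends; each slice j is split at
    necks and compared against its already-refined neighbour i = j -/+ 1, so
    oversegmentations (e.g. leakage into the pectoral muscle) that appear on
    a few slices are discarded.  Never adds voxels except watershed ridge
    voxels between kept components.
    """
    p = p or RefinementParams()
    fg = comp.foreground.copy()
    nz = fg.shape[0]
    if not 0 <= z_ref < nz:
        raise ValueError(f"reference slice {z_ref} outside stack of {nz}")
    # in-plane shift allowance of one slice step, from the voxel anisotropy
    dz, dy, dx = comp.spacing
    dilate_vox = max(int(round(dz / min(dy, dx))) - 1, 0) + 1

    def sweep(rng):
        for i in rng:
            j = i - 1 if rng.step < 0 else i + 1
            # i is the already-refined neighbour of the slice j to refine
            if not fg[i].any() or not fg[j].any():
                continue
            kept, ws, ids = evaluate_components(fg[i], fg[j], p, dilate_vox=dilate_vox)
            fg[j] = update_slice(kept, fg[j].shape, ws, ids, original_mask=fg[j]) == FOREGROUND

    sweep(range(z_ref, 0, -1))  # refine j = i - 1 down to slice 0
    sweep(range(z_ref, nz - 1))  # refine j = i + 1 up to the last slice
    if not fg.any():
        return comp
    return BreastComponent.from_foreground(fg, comp.spacing)


def fill_holes_and_exclude_lower(comp: BreastComponent,
                                 p: RefinementParams | None = None) -> BreastComponent:
    """Fill in-plane holes, then drop the posterior part of the bounding box.

    Holes are filled slice-by-slice; voxels with
    ``y > y1 + lower_exclusion_frac * (y2 - y1)`` of the (post-fill) bounding
    box are removed — they belong to lung and other irrelevant structures.
    """
    p = p or RefinementParams()
    fg = comp.foreground.copy()
    for z in range(fg.shape[0]):
        if fg[z].any():
            fg[z] = ndi.binary_fill_holes(fg[z])
    idx = np.nonzero(fg)
    y1, y2 = int(idx[1].min()), int(idx[1].max())
    y_cut = y1 + p.lower_exclusion_frac * (y2 - y1)
    fg[:, int(np.floor(y_cut)) + 1 :, :] = False
    if not fg.any():
        return comp
    return BreastComponent.from_foreground(fg, comp.spacing)


def _ball_close_mm(fg: np.ndarray, radius_mm: float,
                   spacing: tuple[float, float, float]) -> np.ndarray:
    """Rolling-ball (morphological) closing with a physical ball radius in mm.

    Implemented via two Euclidean distance transforms with anisotropic voxel
    sampling — equivalent to closing with a Euclidean ball of the given
    radius, exact for half-space boundaries and independent of the voxel
    grid.  Restricted to the mask bounding box (padded) for speed.
    """
    if radius_mm < max(spacing):
        warnings.warn(
            f"ball radius {radius_mm} mm below one voxel at spacing {spacing}; clamped to one voxel"
        )
        radius_mm = max(spacing)
    radii = tuple(int(np.ceil(radius_mm / s)) + 1 for s in spacing)
    idx = np.nonzero(fg)
    lo = [max(int(a.min()) - r, 0) for a, r in zip(idx, radii)]
    hi = [min(int(a.max()) + r + 1, n) for a, r, n in zip(idx, radii, fg.shape)]
    box = tuple(slice(a, b) for a, b in zip(lo, hi))
    pad = tuple((r, r) for r in radii)
    a = np.pad(fg[box], pad)
    # half-voxel inflation keeps half-space boundaries exactly invariant under
    # the discrete distance quantization
    r_eff = radius_mm + 0.5 * min(spacing)
    d_bg = ndi.distance_transform_edt(~a, sampling=spacing)
    dilated = a | (d_bg <= r_eff)
    d_fg = ndi.distance_transform_edt(dilated, sampling=spacing)
    closed = d_fg > r_eff
    inner = tuple(slice(r, s - r) for r, s in zip(radii, a.shape))
    out = fg.copy()
    out[box] = closed[inner] | fg[box]
    return out


def close_concavities(comp: BreastComponent, p: RefinementParams | None = None) -> BreastComponent:
    """Region-dependent rolling-ball closing of concavities.

    Three bands of the bounding box get their own kernel: the anterior
    (nipple/areola) band a large ball, foreground adjacent to the posterior
    (pectoral) boundary a medium ball, and the remainder (sides, skin folds)
    a small ball.  The output is a superset of the input.
    """
    p = p or RefinementParams()
    fg = comp.foreground
    (z1, y1, x1), (z2, y2, x2) = comp.bbox
    ny = fg.shape[1]
    yy = np.arange(ny)[None, :, None]

    nipple_band = yy <= y1 + p.nipple_band_frac * (y2 - y1)
    pectoral_band = yy >= y2 - p.pectoral_band_frac * (y2 - y1)
    rest_band = ~nipple_band & ~pectoral_band

    out = fg.copy()
    for band, radius in (
        (nipple_band, p.nipple_ball_mm),
        (pectoral_band, p.pectoral_ball_mm),
        (rest_band, p.side_ball_mm),
    ):
        closed = _ball_close_mm(fg, radius, comp.spacing)
        out |= closed & np.broadcast_to(band, fg.shape)
    return BreastComponent.from_foreground(out, comp.spacing)


def cut_at_sternum(comp: BreastComponent, p: RefinementParams | None = None) -> BreastComponent:
    """Remove everything posterior to the sternum.

    The lowest (largest-y) breast-tissue point within a window around the
    midline ``x_c`` marks the posterior sternum boundary ``y_s``; all voxels
    with ``y > y_s`` are removed.  If the window holds no foreground the
    component is returned unchanged with a warning.
    """
    p = p or RefinementParams()
    fg = comp.foreground
    (_, _, x1), (_, _, x2) = comp.bbox
    x_c = comp.centroid[2]
    half = p.sternum_center_window_frac * (x2 - x1) / 2.0
    nx = fg.shape[2]
    xs = np.arange(nx)
    window = np.abs(xs - x_c) <= half
    if not fg[:, :, window].any():
        warnings.warn("no foreground in the midline window; sternum cut skipped")
        return comp
    ys = np.nonzero(fg[:, :, window].any(axis=(0, 2)))[0]
    y_s = int(ys.max())
    out = fg.copy()
    out[:, y_s + 1 :, :] = False
    logger.info("sternum cut at y=%d", y_s)
    return BreastComponent.from_foreground(out, comp.spacing)


def build_breast_mask(seg3d: BinaryMask, p: RefinementParams | None = None) -> BinaryMask:
    """Full refinement chain from raw fat segmentation to solid breast mask."""
    p = p or RefinementParams()
    comp = extract_largest_component(seg3d)
    z_ref = find_reference_slice(comp, p)
    comp = propagate_boundaries(comp, z_ref, p)
    comp = fill_holes_and_exclude_lower(comp, p)
    comp = close_concavities(comp, p)
    comp = cut_at_sternum(comp, p)
    mask = comp.to_mask()
    lab, n = ndi.label(mask.data, structure=_STRUCT_3D)
    if n > 1:
        sizes = np.bincount(lab.ravel())[1:]
        logger.warning("refined mask has %d components (largest %d voxels)", n, sizes.max())
    return mask
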