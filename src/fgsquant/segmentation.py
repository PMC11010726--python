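"""Tumor mask extraction and contralateral normal-brain ROI construction.

The tumor mask is derived from the nuclear-dye channel, in which the tumor
stands out as the region of high cell density: an automatic two-class
threshold (between-class-variance maximization) is followed by a light
morphological opening, small-component removal, and selection of the
largest connected component.  The normal-brain reference ROI is obtained
by mirroring the tumor mask across the hemispheric midline (same-size,
location-matched contralateral region); an alternative mode takes the
entire contralateral hemisphere's tissue pixels instead.  Because sections
are co-registered, transferring a mask into the fluorescence channel is a
(possibly zero) translation with an explicit bound on lost pixels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.filters import threshold_otsu
from skimage.measure import label as label_components
from skimage.morphology import disk, opening

from .errors import GeometryError, MaskError, SegmentationError, TransferError

__all__ = [
    "RegionMask",
    "segment_tumor",
    "mirror_roi",
    "transfer_mask",
    "hemisphere_roi",
]


@dataclass
class RegionMask:
    """A boolean pixel mask with a semantic label and source channel."""

    pixels: np.ndarray  # H x W bool
    label: str  # "tumor" | "normal" | "tissue"
    source_channel: str = "nuclear"  # "nuclear" | "nir" | "rgb"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=bool)
        if self.pixels.ndim != 2:
            raise MaskError("mask must be a 2-D boolean grid")
        if self.label in ("tumor", "normal") and not self.pixels.any():
            raise MaskError(f"{self.label} mask has no true pixel")

    @property
    def area(self) -> int:
        return int(self.pixels.sum())


def segment_tumor(nuclear: np.ndarray, min_area: int = 25,
                  smoothing_radius: int = 1) -> RegionMask:
    """Segment the tumor from the nuclear-dye channel.

    Otsu's two-class threshold selects high-cell-density pixels; an opening
    with a disk of ``smoothing_radius`` removes speckle, components smaller
    than ``min_area`` are discarded, and the largest remaining connected
    component (8-connectivity) is returned.  Invariant to any positive
    gain applied to the channel.  On a noiseless two-level image the mask
    equals the bright region exactly.
    """
    nuclear = np.asarray(nuclear, dtype=float)
    if nuclear.ndim != 2:
        raise SegmentationError("nuclear channel must be 2-D")
    if np.ptp(nuclear) == 0:
        raise SegmentationError("constant image: no threshold separates it")
    thr = threshold_otsu(nuclear)
    mask = nuclear > thr
    if smoothing_radius > 0:
        mask = opening(mask, disk(smoothing_radius))
    labels, n = label_components(mask, return_num=True)
    if n == 0:
        raise SegmentationError("no foreground component found")
    areas = np.bincount(labels.ravel())[1:]  # skip background
    keep = np.flatnonzero(areas >= min_area)
    if keep.size == 0:
        raise SegmentationError(
            f"no component reaches min_area={min_area} px")
    # largest surviving component; ties resolved by lowest label id
    best = keep[np.argmax(areas[keep])] + 1
    return RegionMask(labels == best, "tumor", "nuclear")


def mirror_roi(tumor_mask: RegionMask, midline_col: int) -> RegionMask:
    """Reflect the tumor mask across the midline column.

    A pixel at column ``c`` maps to ``2*midline_col - c`` (0-based).  The
    tumor must lie entirely on one side of the midline; reflections falling
    outside the image are dropped but must account for < 1% of the mask.
    """
    pix = tumor_mask.pixels
    H, W = pix.shape
    rows, cols = np.nonzero(pix)
    if rows.size == 0:
        raise MaskError("empty tumor mask")
    if cols.min() <= midline_col <= cols.max():
        raise GeometryError("tumor mask straddles (or touches) the midline")
    ref_cols = 2 * midline_col - cols
    inside = (ref_cols >= 0) & (ref_cols < W)
    lost = rows.size - int(inside.sum())
    if lost / rows.size >= 0.01:
        raise GeometryError(
            f"{lost}/{rows.size} reflected pixels fall outside the image")
    out = np.zeros_like(pix)
    out[rows[inside], ref_cols[inside]] = True
    return RegionMask(out, "normal", tumor_mask.source_channel)


def transfer_mask(mask: RegionMask, target_shape: tuple[int, int],
                  offset: tuple[int, int] = (0, 0)) -> RegionMask:
    """Translate a mask into a co-registered target image.

    Sections are co-registered, so the target shape must match and the
    offset defaults to zero.  Pixels shifted out of bounds are dropped; if
    more than 10% of the mask would be lost the transfer is refused.
    """
    pix = mask.pixels
    if tuple(target_shape) != pix.shape:
        raise GeometryError(
            f"target shape {tuple(target_shape)} != mask shape {pix.shape}")
    dr, dc = offset
    rows, cols = np.nonzero(pix)
    nr, nc = rows + dr, cols + dc
    inside = (nr >= 0) & (nr < pix.shape[0]) & (nc >= 0) & (nc < pix.shape[1])
    lost = rows.size - int(inside.sum())
    if rows.size and lost / rows.size > 0.10:
        raise TransferError(
            f"offset {offset} would drop {lost}/{rows.size} mask pixels")
    out = np.zeros_like(pix)
    out[nr[inside], nc[inside]] = True
    return RegionMask(out, mask.label, mask.source_channel)


def hemisphere_roi(nuclear: np.ndarray, midline_col: int,
                   tumor_mask: RegionMask,
                   tissue_quantile: float = 0.05) -> RegionMask:
    """Whole contralateral hemisphere as the normal-brain ROI.

    Tissue pixels are those whose nuclear intensity exceeds a low quantile
    of the channel; the ROI is their restriction to the hemisphere opposite
    the tumor (the midline column itself is excluded).
    """
    nuclear = np.asarray(nuclear, dtype=float)
    cols = np.nonzero(tumor_mask.pixels)[1]
    if cols.size == 0:
        raise MaskError("empty tumor mask")
    if cols.min() <= midline_col <= cols.max():
        raise GeometryError("tumor mask straddles the midline")
    tumor_on_right = cols.min() > midline_col
    thr = np.quantile(nuclear, tissue_quantile)
    tissue = nuclear > thr
    col_idx = np.arange(nuclear.shape[1])
    side = col_idx < midline_col if tumor_on_right else col_idx > midline_col
    out = tissue & side[None, :]
    if not out.any():
        raise MaskError("contralateral hemisphere contains no tissue pixel")
    return RegionMask(out, "normal", "nuclear")
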