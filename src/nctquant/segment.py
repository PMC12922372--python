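"""Per-cell compartment model: nucleus, whole cell, cytosol, envelope rings.

The compartments mirror how the quantified structures are defined in
practice: the DNA stain (DAPI) sets the nuclear boundary, a cytosolic marker
(ChAT/NeuN, Vimentin, ...) sets the cell boundary, the laminar ring is the
annulus between the nucleus edge and its morphological dilation (default
1.3 µm), and the flow-cytometry-style cytosol is simply
"whole cell AND NOT nucleus".
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.morphology import disk as disk_footprint
from skimage.segmentation import watershed

from .image import ChannelImage, um_to_px

__all__ = [
    "SegmentedCell",
    "threshold_image",
    "segment_nuclei",
    "segment_cells",
    "make_ring",
    "perinuclear_band",
    "estimate_background",
]

logger = logging.getLogger(__name__)

_S8 = np.ones((3, 3), dtype=int)  # 8-connectivity


@dataclass
class SegmentedCell:
    """Boolean compartment masks for one cell, congruent with the image.

    ``cytosol_mask`` is derived on construction as
    ``cell_mask & ~nucleus_mask`` and ``nucleus_mask ⊆ cell_mask`` is
    enforced, so the masks can never disagree.
    """

    cell_id: int
    nucleus_mask: np.ndarray
    cell_mask: np.ndarray
    ring_mask: np.ndarray | None = None
    ring_params: tuple[float, float] | None = None  # (inner µm, outer µm)
    cytosol_mask: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.nucleus_mask = np.asarray(self.nucleus_mask, dtype=bool)
        self.cell_mask = np.asarray(self.cell_mask, dtype=bool)
        if self.nucleus_mask.shape != self.cell_mask.shape:
            raise ValueError("nucleus and cell masks must be congruent")
        if not self.nucleus_mask.any():
            raise ValueError(f"cell {self.cell_id}: empty nucleus mask")
        if np.any(self.nucleus_mask & ~self.cell_mask):
            raise ValueError(f"cell {self.cell_id}: nucleus not contained in cell mask")
        self.cytosol_mask = self.cell_mask & ~self.nucleus_mask

    def with_ring(self, inner_um: float, outer_um: float, pixel_size: float) -> "SegmentedCell":
        """Return a copy carrying the laminar ring for the given offsets."""
        ring = make_ring(self.nucleus_mask, outer_um, inner_um, pixel_size)
        return SegmentedCell(
            cell_id=self.cell_id,
            nucleus_mask=self.nucleus_mask,
            cell_mask=self.cell_mask,
            ring_mask=ring,
            ring_params=(inner_um, outer_um),
        )


def threshold_image(
    pixels: np.ndarray, method: str = "otsu", value: float | None = None
) -> float:
    """Global threshold: Otsu (default), a fixed value, or a percentile.

    ``method`` is one of ``"otsu"``, ``"fixed"`` (requires ``value``), or
    ``"percentile"`` (``value`` = percentile in [0, 100]).
    """
    if method == "otsu":
        if np.ptp(pixels) == 0:
            raise ValueError("no threshold separates foreground: image is constant")
        return float(threshold_otsu(pixels))
    if method == "fixed":
        if value is None:
            raise ValueError("fixed thresholding requires a value")
        return float(value)
    if method == "percentile":
        if value is None:
            raise ValueError("percentile thresholding requires a value")
        return float(np.percentile(pixels, value))
    raise ValueError(f"unknown threshold method '{method}'")


def segment_nuclei(
    dna: ChannelImage,
    min_area_um2: float,
    method: str = "otsu",
    threshold_value: float | None = None,
) -> list[np.ndarray]:
    """Segment nuclei from the DNA-stain channel.

    Global threshold → fill holes → drop components smaller than
    ``min_area_um2`` → label. Returns one boolean mask per retained nucleus;
    masks are disjoint by construction.
    """
    thr = threshold_image(dna.pixels, method=method, value=threshold_value)
    fg = dna.pixels > thr
    fg = ndimage.binary_fill_holes(fg)
    labels, n = ndimage.label(fg, structure=_S8)
    min_px = min_area_um2 / dna.pixel_area_um2()
    masks = []
    for i in range(1, n + 1):
        m = labels == i
        if m.sum() >= min_px:
            masks.append(m)
    return masks


def segment_cells(
    marker: ChannelImage,
    nuclei: list[np.ndarray],
    method: str = "otsu",
    threshold_value: float | None = None,
) -> list[SegmentedCell]:
    """Segment whole cells from a cytosolic marker, paired to nuclei.

    The marker is thresholded; each foreground component is assigned the
    nuclei it contains. Components holding two or more nuclei are split by a
    geodesic nearest-nucleus partition (marker-constrained watershed). Cells
    whose nucleus has no surrounding marker foreground keep
    ``cell_mask == nucleus_mask`` (the nucleus is always union-enforced into
    its cell); nuclei are never discarded silently.
    """
    if not nuclei:
        raise ValueError("segment_cells requires at least one nucleus")
    thr = threshold_image(marker.pixels, method=method, value=threshold_value)
    fg = ndimage.binary_fill_holes(marker.pixels > thr)

    markers = np.zeros(marker.shape, dtype=np.int32)
    for i, nuc in enumerate(nuclei, start=1):
        markers[nuc] = i
    # geodesic nearest-nucleus partition of the foreground
    partition = watershed(np.zeros(marker.shape), markers=markers, mask=fg | (markers > 0))

    cells = []
    for i, nuc in enumerate(nuclei, start=1):
        cell = partition == i
        # keep only the component of the cell region that contains the nucleus
        labels, n = ndimage.label(cell | nuc, structure=_S8)
        nucleus_label = labels[nuc][0]
        cell = labels == nucleus_label
        cell |= nuc
        if not np.any(cell & ~nuc):
            warnings.warn(
                f"cell {i}: no marker foreground around the nucleus; "
                "cell mask equals nucleus mask and cytosol is empty",
                stacklevel=2,
            )
        cells.append(SegmentedCell(cell_id=i, nucleus_mask=nuc, cell_mask=cell))
    return cells


def _dilate_um(mask: np.ndarray, offset_um: float, pixel_size: float) -> np.ndarray:
    r = um_to_px(offset_um, pixel_size)
    if r == 0:
        return mask.copy()
    return ndimage.binary_dilation(mask, structure=disk_footprint(r))


def make_ring(
    nucleus_mask: np.ndarray,
    outer_offset_um: float,
    inner_offset_um: float,
    pixel_size: float,
) -> np.ndarray:
    """Annulus between two dilations of the nucleus.

    ``ring = dilate(nucleus, outer) & ~dilate(nucleus, inner)`` with disk
    structuring elements of radius ``round(offset / pixel_size)`` (half-up).
    The default laminar ring uses inner 0 µm, outer 1.3 µm.
    """
    if inner_offset_um < 0 or outer_offset_um <= inner_offset_um:
        raise ValueError(
            f"offsets must satisfy 0 <= inner < outer, got inner={inner_offset_um}, "
            f"outer={outer_offset_um}"
        )
    outer_px = um_to_px(outer_offset_um, pixel_size)
    inner_px = um_to_px(inner_offset_um, pixel_size)
    if outer_px <= inner_px:
        raise ValueError(
            f"outer offset {outer_offset_um} µm and inner offset {inner_offset_um} µm "
            f"round to the same pixel radius at {pixel_size} µm/px; the minimum "
            f"resolvable offset difference is one pixel ({pixel_size} µm)"
        )
    outer = _dilate_um(nucleus_mask, outer_offset_um, pixel_size)
    inner = _dilate_um(nucleus_mask, inner_offset_um, pixel_size)
    return outer & ~inner


def perinuclear_band(
    nucleus_mask: np.ndarray, width_um: float, pixel_size: float
) -> np.ndarray:
    """Cytoplasmic band of the given width immediately around the nucleus.

    Alias of :func:`make_ring` with inner offset 0; used for the
    perinuclear cytoplasmic XPO1 measurement in post-mortem tissue, where
    the relevant cytoplasm is a narrow band rather than the full cytosol.
    """
    return make_ring(nucleus_mask, width_um, 0.0, pixel_size)


def estimate_background(
    image: ChannelImage, all_cell_masks: list[np.ndarray], guard_px: int = 2
) -> tuple[float, str]:
    """Background level from pixels outside every cell.

    The union of cell masks is dilated by ``guard_px`` pixels as a guard
    band; the default statistic is the median of the remaining pixels.
    Returns ``(value, statistic_name)``.
    """
    union = np.zeros(image.shape, dtype=bool)
    for m in all_cell_masks:
        union |= m
    if guard_px > 0:
        union = ndimage.binary_dilation(union, structure=disk_footprint(guard_px))
    bg = ~union
    if not bg.any():
        raise ValueError(
            "no pixels outside the cell masks; supply a manual background value"
        )
    return float(np.median(image.pixels[bg])), "median_outside_cells"
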