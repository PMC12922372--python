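"""Per-cell image metrics for nucleocytoplasmic-transport quantification.

All intensity metrics operate on a :class:`~nctquant.image.ChannelImage`
plus boolean compartment masks, subtract an explicit background where the
metric calls for it, and return plain floats. Undefined ratios (non-positive
denominators) raise :class:`UndefinedMetric` so callers can exclude and log
the cell rather than silently clipping.

Implemented quantities:

* ``cn_ratio`` / ``nc_gradient`` — background-subtracted cytosol-to-nucleus
  (resp. nucleus-to-cytosol) mean-intensity ratio, the canonical readout of
  transport-factor mislocalization.
* ``laminar_intensity`` — mean marker intensity in the envelope annulus
  (nucleus edge → 1.3 µm dilation by default).
* ``envelope_to_nucleoplasm_ratio`` — 1-px envelope band normalised by the
  nucleoplasm, the post-mortem-tissue variant.
* ``detect_puncta`` and aggregations — thresholded connected components with
  area, roundness and envelope-proximity filters.
* ``envelope_profile`` / ``continuity_index`` — intensity along the traced
  nuclear boundary; the continuity index is supra-threshold arc length over
  perimeter (1 = unbroken rim).
* ``circularity`` — 4π·area / perimeter².
* ``colocalization_ratio`` — overlap area of two thresholded channels over
  the reference channel's area.
* ``line_profile`` — bilinear intensity profile along a segment.
* ``normalize_to_control`` — per-experiment normalisation to the control
  group's mean.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.morphology import disk as disk_footprint

from .image import ChannelImage, um_to_px
from .trace import boundary_path_and_arcs, step_lengths

__all__ = [
    "UndefinedMetric",
    "PunctaSet",
    "EnvelopeProfile",
    "mask_mean",
    "cn_ratio",
    "nc_gradient",
    "laminar_intensity",
    "envelope_to_nucleoplasm_ratio",
    "detect_puncta",
    "puncta_count",
    "puncta_size_summary",
    "envelope_profile",
    "continuity_index",
    "default_continuity_threshold",
    "circularity",
    "colocalization_ratio",
    "line_profile",
    "normalize_to_control",
]

logger = logging.getLogger(__name__)


class UndefinedMetric(ValueError):
    """A metric is undefined for this cell (e.g. non-positive denominator)."""


def mask_mean(image: ChannelImage, mask: np.ndarray) -> float:
    """Mean intensity over a boolean mask (errors on an empty mask)."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != image.shape:
        raise ValueError("mask not congruent with image")
    n = int(mask.sum())
    if n == 0:
        raise UndefinedMetric("empty mask")
    return float(image.pixels[mask].sum() / n)


def cn_ratio(image: ChannelImage, cell, background: float) -> float:
    """Background-subtracted cytosol-to-nucleus mean intensity ratio."""
    nuc = mask_mean(image, cell.nucleus_mask) - background
    if not cell.cytosol_mask.any():
        raise UndefinedMetric(f"cell {cell.cell_id}: empty cytosol")
    cyt = mask_mean(image, cell.cytosol_mask) - background
    if nuc <= 0:
        raise UndefinedMetric(
            f"cell {cell.cell_id}: background-subtracted nuclear mean {nuc:.3g} <= 0"
        )
    return cyt / nuc


def nc_gradient(image: ChannelImage, cell, background: float) -> float:
    """Nucleus-to-cytosol ratio (reciprocal orientation of :func:`cn_ratio`)."""
    if not cell.cytosol_mask.any():
        raise UndefinedMetric(f"cell {cell.cell_id}: empty cytosol")
    cyt = mask_mean(image, cell.cytosol_mask) - background
    nuc = mask_mean(image, cell.nucleus_mask) - background
    if cyt <= 0:
        raise UndefinedMetric(
            f"cell {cell.cell_id}: background-subtracted cytosol mean {cyt:.3g} <= 0"
        )
    return nuc / cyt


def laminar_intensity(image: ChannelImage, ring_mask: np.ndarray, background: float) -> float:
    """Mean intensity over the envelope ring minus background.

    Not clipped: a value below zero is returned as-is (and worth flagging
    upstream), never silently set to zero.
    """
    return mask_mean(image, ring_mask) - background


def envelope_to_nucleoplasm_ratio(
    image: ChannelImage,
    nucleus_mask: np.ndarray,
    band_px: int = 1,
) -> float:
    """1-px envelope band mean over nucleoplasm mean.

    The envelope band is the ``band_px``-wide ring just outside the nucleus;
    the nucleoplasm is the nucleus eroded by the same width, so the band and
    its normaliser never share pixels. No external background enters: the
    nucleoplasm is the normaliser.
    """
    if band_px < 1:
        raise ValueError("band_px must be >= 1")
    se = disk_footprint(band_px)
    band = ndimage.binary_dilation(nucleus_mask, structure=se) & ~nucleus_mask
    nucleoplasm = ndimage.binary_erosion(nucleus_mask, structure=se)
    if not nucleoplasm.any():
        raise UndefinedMetric("nucleus too small to erode for a nucleoplasm estimate")
    nuc = mask_mean(image, nucleoplasm)
    if nuc <= 0:
        raise UndefinedMetric("nucleoplasm mean <= 0")
    return mask_mean(image, band) / nuc


# ---------------------------------------------------------------------------
# puncta


@dataclass
class PunctaSet:
    """Detected puncta plus the detection parameters that produced them."""

    table: pd.DataFrame  # area_um2, centroid_row, centroid_col, mean_intensity,
    #                      roundness, dist_to_envelope_um
    params: dict

    def __len__(self) -> int:
        return len(self.table)


def _component_roundness(mask: np.ndarray, pixel_size: float) -> float:
    """4π·area/perimeter² of one connected component; 1.0 for tiny blobs.

    Components too small to carry a meaningful digital perimeter (< 4 px)
    are round by convention.
    """
    n = int(mask.sum())
    if n < 4:
        return 1.0
    from .trace import trace_boundary

    path = trace_boundary(mask)
    perim = float(step_lengths(path).sum()) * pixel_size
    area = n * pixel_size**2
    if perim <= 0:
        return 1.0
    return min(4 * np.pi * area / perim**2, 1.0)


def detect_puncta(
    image: ChannelImage,
    region_mask: np.ndarray,
    intensity_threshold: float,
    min_area_um2: float,
    max_area_um2: float,
    min_roundness: float | None = None,
    max_dist_to_envelope_um: float | None = None,
    nucleus_mask: np.ndarray | None = None,
) -> PunctaSet:
    """Call puncta as thresholded connected components with shape filters.

    Components of ``image > intensity_threshold`` inside ``region_mask`` are
    kept when their area lies in ``[min_area_um2, max_area_um2]``, then
    optionally filtered by roundness (4π·area/perimeter² ≥ ``min_roundness``)
    and by centroid distance to the nuclear boundary
    (≤ ``max_dist_to_envelope_um``; requires ``nucleus_mask``).
    """
    if min_area_um2 >= max_area_um2:
        raise ValueError(
            f"min_area_um2 ({min_area_um2}) must be smaller than max_area_um2 "
            f"({max_area_um2})"
        )
    if max_dist_to_envelope_um is not None and nucleus_mask is None:
        raise ValueError("the envelope-distance filter requires nucleus_mask")

    fg = (image.pixels > intensity_threshold) & np.asarray(region_mask, dtype=bool)
    labels, n = ndimage.label(fg, structure=np.ones((3, 3), dtype=int))

    dist_to_boundary = None
    if max_dist_to_envelope_um is not None:
        # distance (µm) from any pixel to the nucleus boundary
        nuc = np.asarray(nucleus_mask, dtype=bool)
        boundary = nuc & ~ndimage.binary_erosion(nuc)
        dist_to_boundary = ndimage.distance_transform_edt(~boundary) * image.pixel_size

    px_area = image.pixel_area_um2()
    rows = []
    for i in range(1, n + 1):
        comp = labels == i
        area = comp.sum() * px_area
        if not (min_area_um2 <= area <= max_area_um2):
            continue
        r, c = np.nonzero(comp)
        centroid = (float(r.mean()), float(c.mean()))
        roundness = _component_roundness(comp, image.pixel_size)
        if min_roundness is not None and roundness < min_roundness:
            continue
        dist = np.nan
        if dist_to_boundary is not None:
            dist = float(
                dist_to_boundary[int(round(centroid[0])), int(round(centroid[1]))]
            )
            if dist > max_dist_to_envelope_um:
                continue
        rows.append(
            {
                "area_um2": float(area),
                "centroid_row": centroid[0],
                "centroid_col": centroid[1],
                "mean_intensity": float(image.pixels[comp].mean()),
                "roundness": float(roundness),
                "dist_to_envelope_um": dist,
            }
        )
    cols = [
        "area_um2",
        "centroid_row",
        "centroid_col",
        "mean_intensity",
        "roundness",
        "dist_to_envelope_um",
    ]
    table = pd.DataFrame(rows, columns=cols)
    params = {
        "intensity_threshold": intensity_threshold,
        "min_area_um2": min_area_um2,
        "max_area_um2": max_area_um2,
        "min_roundness": min_roundness,
        "max_dist_to_envelope_um": max_dist_to_envelope_um,
    }
    return PunctaSet(table=table, params=params)


def puncta_count(puncta: PunctaSet) -> int:
    return len(puncta)


def puncta_size_summary(puncta: PunctaSet) -> tuple[int, float]:
    """(count, mean area µm²); mean is NaN for an empty set."""
    n = len(puncta)
    mean_area = float(puncta.table["area_um2"].mean()) if n else float("nan")
    return n, mean_area


# ---------------------------------------------------------------------------
# envelope profile / continuity


@dataclass
class EnvelopeProfile:
    """Intensity along the traced nuclear boundary.

    ``path`` is the closed boundary pixel trace (the start pixel repeated at
    the end), ``arc_um`` the strictly increasing arc-length positions with
    ``arc_um[-1] == perimeter_um``, and ``intensity[i]`` the envelope signal
    sampled at boundary position i (maximum over the annulus pixels within a
    window of the local ring width).
    """

    path: np.ndarray
    arc_um: np.ndarray
    intensity: np.ndarray
    perimeter_um: float
    pixel_size: float


def envelope_profile(
    image: ChannelImage,
    nucleus_mask: np.ndarray,
    ring_width_um: float = 1.3,
    *,
    calibrated: bool = True,
) -> EnvelopeProfile:
    """Sample envelope intensity along the nucleus boundary.

    The nucleus boundary is traced in a fixed orientation starting at the
    topmost-then-leftmost boundary pixel. At each boundary pixel the envelope
    intensity is the maximum of the image sampled (bilinearly) along the
    outward normal over the local ring width — the strongest rim signal on
    the ray through that boundary position, so a gap in the rim cannot be
    masked by signal a few pixels away along the rim. The outward normal is
    approximated by the ray from the nucleus centroid (exact for circles,
    adequate for the modest eccentricities of real nuclei). Arc length uses
    the package's digital arc-length rule, so the profile's perimeter
    matches :func:`circularity`.
    """
    nuc = np.asarray(nucleus_mask, dtype=bool)
    filled = ndimage.binary_fill_holes(nuc)
    if filled.sum() != nuc.sum():
        raise ValueError("nucleus mask must be simply connected (no holes)")
    w_px = max(um_to_px(ring_width_um, image.pixel_size), 1)

    path, arc, perim = boundary_path_and_arcs(nuc, image.pixel_size, calibrated=calibrated)
    rr, cc = np.nonzero(nuc)
    centroid = np.array([rr.mean(), cc.mean()])
    dirs = path - centroid
    norms = np.linalg.norm(dirs, axis=1)
    norms[norms == 0] = 1.0
    dirs = dirs / norms[:, None]
    # radial sample offsets from just outside the boundary pixel to the
    # outer edge of the annulus
    ts = np.arange(0.5, w_px + 0.75, 0.5)
    pts = path[:, None, :] + dirs[:, None, :] * ts[None, :, None]
    vals = ndimage.map_coordinates(
        image.pixels, [pts[..., 0].ravel(), pts[..., 1].ravel()], order=1, mode="nearest"
    ).reshape(len(path), len(ts)).max(axis=1)

    # close the trace: repeat the start point at arc position == perimeter
    path_closed = np.vstack([path, path[:1]])
    arc_closed = np.concatenate([arc, [perim]])
    vals_closed = np.concatenate([vals, vals[:1]])
    return EnvelopeProfile(
        path=path_closed,
        arc_um=arc_closed,
        intensity=vals_closed,
        perimeter_um=perim,
        pixel_size=image.pixel_size,
    )


def default_continuity_threshold(
    profile_or_image, ring_mask: np.ndarray | None = None, background: float = 0.0
) -> float:
    """Half-way rule: background + 0.5·(rim signal level − background).

    The rim signal level is estimated as the 90th percentile of the rim
    intensities, so the rule stays well-defined whatever fraction of the
    rim is missing (a plain median collapses onto the binarization boundary
    exactly when half the rim is gone). Accepts either an
    :class:`EnvelopeProfile` (percentile of its intensities) or a
    ChannelImage plus ring mask.
    """
    if isinstance(profile_or_image, EnvelopeProfile):
        ref = float(np.percentile(profile_or_image.intensity, 90))
    else:
        ref = float(
            np.percentile(profile_or_image.pixels[np.asarray(ring_mask, dtype=bool)], 90)
        )
    return background + 0.5 * max(ref - background, 0.0)


def continuity_index(
    profile: EnvelopeProfile, signal_threshold: float
) -> tuple[float, int, int]:
    """Supra-threshold arc length over perimeter, with fragment/gap counts.

    The profile is binarized at ``signal_threshold``; the index is the total
    supra-threshold arc length divided by the perimeter (1 = unbroken rim,
    lower = more discontinuity). Fragments are maximal supra-threshold runs,
    gaps maximal sub-threshold runs, both counted circularly (runs wrapping
    the trace start are merged). Binarization is strict (``> threshold``),
    so a threshold equal to the background classifies pure-background rim
    positions as gap.
    """
    supra = profile.intensity[:-1] > signal_threshold  # drop duplicated closing point
    steps = np.diff(profile.arc_um)  # length N, step i leaves pixel i
    total = float(profile.perimeter_um)
    supra_len = float(steps[supra].sum())
    index = min(supra_len / total, 1.0) if total > 0 else 0.0

    n = len(supra)
    if n == 0:
        return 0.0, 0, 0
    if supra.all():
        return 1.0, 1, 0
    if not supra.any():
        return 0.0, 0, 1
    # circular run counting: number of False->True transitions = fragments
    prev = np.roll(supra, 1)
    fragments = int(np.sum(supra & ~prev))
    gaps = int(np.sum(~supra & prev))
    return index, fragments, gaps


# ---------------------------------------------------------------------------
# shape / colocalization / profiles


def circularity(mask: np.ndarray, pixel_size: float, *, calibrated: bool = True) -> float:
    """4π·area / perimeter² for a single-component mask.

    Area is the pixel count times the pixel area; the perimeter comes from
    the same digital boundary walk used by the envelope profile, so shape
    and continuity quantities share one perimeter definition.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("circularity of an empty mask is undefined")
    _, _, perim = boundary_path_and_arcs(mask, pixel_size, calibrated=calibrated)
    area = mask.sum() * pixel_size**2
    return float(4 * np.pi * area / perim**2)


def colocalization_ratio(
    chan_a: ChannelImage,
    chan_b: ChannelImage,
    threshold_a: float,
    threshold_b: float,
    region: np.ndarray | None = None,
) -> float:
    """Overlap area of the two thresholded masks over the A-mask area.

    ``|(A > tA) & (B > tB)| / |(A > tA)|``, optionally restricted to a
    region; a per-image statistic in [0, 1].
    """
    if chan_a.shape != chan_b.shape:
        raise ValueError("channels must be congruent")
    mask_a = chan_a.pixels > threshold_a
    mask_b = chan_b.pixels > threshold_b
    if region is not None:
        region = np.asarray(region, dtype=bool)
        mask_a &= region
        mask_b &= region
    area_a = int(mask_a.sum())
    if area_a == 0:
        raise UndefinedMetric("reference channel has no suprathreshold area")
    return float((mask_a & mask_b).sum() / area_a)


def line_profile(
    images: list[ChannelImage] | ChannelImage,
    p0: tuple[float, float],
    p1: tuple[float, float],
    n_samples: int = 100,
) -> pd.DataFrame:
    """Bilinear intensity profile along the segment p0→p1 (row, col).

    Returns a tidy frame with ``distance_um`` plus one column per channel;
    used for the line-scan colocalization displays.
    """
    if isinstance(images, ChannelImage):
        images = [images]
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    if np.allclose(p0, p1):
        raise ValueError("line endpoints coincide")
    shape = images[0].shape
    for im in images:
        if im.shape != shape:
            raise ValueError("all channels must be congruent")
        for p in (p0, p1):
            if not (0 <= p[0] <= shape[0] - 1 and 0 <= p[1] <= shape[1] - 1):
                raise ValueError(f"endpoint {tuple(p)} outside image {shape}")
    t = np.linspace(0.0, 1.0, n_samples)
    rows = p0[0] + t * (p1[0] - p0[0])
    cols = p0[1] + t * (p1[1] - p0[1])
    dist = np.hypot(rows - p0[0], cols - p0[1]) * images[0].pixel_size
    out = {"distance_um": dist}
    for im in images:
        out[im.channel_name or f"ch{len(out)}"] = ndimage.map_coordinates(
            im.pixels, [rows, cols], order=1, mode="nearest"
        )
    return pd.DataFrame(out)


def normalize_to_control(
    table: pd.DataFrame,
    control_group: str,
    group_col: str = "group",
    experiment_col: str = "experiment_id",
    value_col: str = "value",
) -> pd.DataFrame:
    """Divide every value by its experiment's control-group mean.

    After normalisation the control group's mean is 1 within each
    experiment. Raises if any experiment lacks control rows.
    """
    out = table.copy()
    for exp, sub in table.groupby(experiment_col):
        ctrl = sub.loc[sub[group_col] == control_group, value_col]
        if ctrl.empty:
            raise ValueError(
                f"experiment '{exp}' has no rows for control group '{control_group}'"
            )
        mean = ctrl.mean()
        if mean == 0:
            raise ValueError(f"experiment '{exp}': control mean is zero")
        out.loc[sub.index, value_col] = sub[value_col] / mean
    return out
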