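"""Synthetic fluorescence-microscopy scenes and clustered cohorts.

No raw images accompany the study design this package implements, so every
metric and the statistics stack are validated against simulated data with
known ground truth. A *scene* is a multi-channel 2-D image of non-overlapping
cells, each an elliptical nucleus inside a larger elliptical cell, on a flat
background. Each marker channel can plant, per cell:

* a cytosol-to-nucleus intensity ratio (``cytosol_level / nucleus_level``),
* a nuclear-envelope ring of given width with a planted gap fraction
  (contiguous arcs of missing rim signal),
* cytoplasmic puncta of known count, radius and intensity,
* a thresholded-mask overlap fraction against another channel.

Channel composition is additive: ``background + nucleus_level·nucleus +
cytosol_level·cytosol + ring_level·ring + punctum_level·puncta``. Shot noise
(Poisson on the composed signal) and Gaussian read noise are applied after
rasterization. A fixed seed fully determines the output.

A *cohort* is the tabular counterpart: groups → clusters (animals / lines /
experiments) → cells, with additive group effects, Gaussian cluster random
intercepts and cell-level residuals, giving a known intra-cluster
correlation — the test bed for the cluster-robust rank statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.morphology import disk as disk_footprint

from .image import ChannelImage, um_to_px

__all__ = [
    "MarkerSpec",
    "SceneSpec",
    "CohortDesign",
    "GroundTruth",
    "generate_scene",
    "generate_cohort",
]

DNA_CHANNEL = "DNA"


@dataclass
class MarkerSpec:
    """Planted ground-truth parameters for one marker channel.

    ``cytosol_level / nucleus_level`` is the planted C/N ratio (defined only
    when ``nucleus_level > 0``). ``gap_fraction`` is the fraction of the
    nuclear perimeter carrying no ring signal. For overlap channels
    (``overlap_with`` set) the marker plants no structures of its own;
    ``cytosol_level`` doubles as its foreground intensity.
    """

    name: str
    nucleus_level: float = 0.0
    cytosol_level: float = 0.0
    ring_level: float = 0.0
    ring_width_um: float = 1.3
    gap_fraction: float = 0.0
    n_puncta: int = 0
    punctum_radius_um: float = 0.6
    punctum_level: float = 0.0
    overlap_with: tuple[str, float] | None = None

    def __post_init__(self) -> None:
        for attr in ("nucleus_level", "cytosol_level", "ring_level", "punctum_level"):
            if getattr(self, attr) < 0:
                raise ValueError(f"{attr} must be >= 0")
        if not 0.0 <= self.gap_fraction <= 1.0:
            raise ValueError(f"gap_fraction must be in [0, 1], got {self.gap_fraction}")
        if self.n_puncta < 0:
            raise ValueError("n_puncta must be >= 0")
        if self.overlap_with is not None:
            other, frac = self.overlap_with
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"overlap fraction must be in [0, 1], got {frac}")
            self.overlap_with = (str(other), float(frac))

    @property
    def true_cn(self) -> float | None:
        """Planted cytosol-to-nucleus ratio, if defined."""
        if self.nucleus_level > 0:
            return self.cytosol_level / self.nucleus_level
        return None


@dataclass
class SceneSpec:
    """Full specification of one synthetic multi-channel scene."""

    image_shape: tuple[int, int] = (256, 256)
    pixel_size: float = 0.325
    n_cells: int = 8
    nucleus_radius_um: tuple[float, float] = (4.0, 0.4)  # (mean, sd)
    cell_radius_um: tuple[float, float] = (8.0, 0.8)
    background_level: float = 10.0
    markers: list[MarkerSpec] = field(default_factory=list)
    gaussian_sd: float = 0.0
    poisson: bool = False
    dna_level: float = 300.0
    max_axis_ratio: float = 1.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.nucleus_radius_um[0] >= self.cell_radius_um[0]:
            raise ValueError("mean nucleus radius must be smaller than mean cell radius")
        if self.background_level < 0 or self.dna_level < 0:
            raise ValueError("intensities must be >= 0")
        if self.gaussian_sd < 0:
            raise ValueError("gaussian_sd must be >= 0")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if not 1.0 <= self.max_axis_ratio <= 1.5:
            raise ValueError("max_axis_ratio must lie in [1, 1.5]")
        names = [m.name for m in self.markers]
        if len(set(names)) != len(names):
            raise ValueError("marker names must be unique")


@dataclass
class CohortDesign:
    """Clustered cohort: groups → clusters → cells on a latent scale."""

    group_effects: tuple[float, ...] = (0.0, 0.0, 0.0)
    clusters_per_group: int = 5
    cells_per_cluster: int = 40
    cluster_sd: float = 1.0
    cell_sd: float = 1.0
    distribution: str = "gaussian"
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.group_effects) < 2:
            raise ValueError("need at least 2 groups")
        if self.clusters_per_group < 2:
            raise ValueError(
                "clusters_per_group must be >= 2: with a single cluster per group "
                "the cluster-level variance is not estimable"
            )
        if self.cells_per_cluster < 1:
            raise ValueError("cells_per_cluster must be >= 1")
        if self.cluster_sd < 0 or self.cell_sd <= 0:
            raise ValueError("cluster_sd must be >= 0 and cell_sd > 0")
        if self.distribution not in ("gaussian", "lognormal"):
            raise ValueError("distribution must be 'gaussian' or 'lognormal'")

    @property
    def icc(self) -> float:
        """Design intra-cluster correlation cluster_sd²/(cluster_sd²+cell_sd²)."""
        return self.cluster_sd**2 / (self.cluster_sd**2 + self.cell_sd**2)


@dataclass
class GroundTruth:
    """Everything the generator knows about a scene, for validation."""

    nucleus_labels: np.ndarray
    cell_labels: np.ndarray
    cells: pd.DataFrame
    ring_signal_masks: dict[str, np.ndarray]
    ring_band_masks: dict[str, np.ndarray]
    structure_masks: dict[str, np.ndarray]
    puncta_centroids: dict[str, dict[int, np.ndarray]]
    overlap_fraction: dict[str, float]

    def nucleus_mask(self, cell_id: int) -> np.ndarray:
        return self.nucleus_labels == cell_id

    def cell_mask(self, cell_id: int) -> np.ndarray:
        return self.cell_labels == cell_id

    def to_csv(self, path: str | Path) -> None:
        """Write the per-cell ground-truth table."""
        self.cells.to_csv(path, index=False)


def _rasterize_ellipse(
    shape: tuple[int, int], center: tuple[float, float], a: float, b: float, theta: float
) -> np.ndarray:
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    dr = rr - center[0]
    dc = cc - center[1]
    ct, st = np.cos(theta), np.sin(theta)
    u = dc * ct + dr * st
    v = -dc * st + dr * ct
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def _place_cells(spec: SceneSpec, rng: np.random.Generator) -> list[dict]:
    """Rejection-sample non-overlapping cell geometries."""
    h, w = spec.image_shape
    px = spec.pixel_size
    cells: list[dict] = []
    max_tries = 300 * spec.n_cells
    tries = 0
    while len(cells) < spec.n_cells:
        tries += 1
        if tries > max_tries:
            raise RuntimeError(
                f"could not place {spec.n_cells} non-overlapping cells of mean radius "
                f"{spec.cell_radius_um[0]} µm in a {h}x{w} px image at {px} µm/px "
                f"after {max_tries} tries; reduce n_cells or the cell radius"
            )
        r_nuc = max(rng.normal(*spec.nucleus_radius_um), 2.1 * px)
        r_cell = rng.normal(*spec.cell_radius_um)
        q = rng.uniform(1.0, spec.max_axis_ratio)
        a = r_nuc * np.sqrt(q) / px  # semi-axes in px
        b = r_nuc / np.sqrt(q) / px
        # guarantee a usable cytosolic rim of >= 2 µm around the nucleus
        r_cell_px = max(r_cell / px, max(a, b) + max(3.0, 2.0 / px))
        theta = rng.uniform(0, np.pi)
        margin = r_cell_px + 2.0
        if 2 * margin >= min(h, w):
            continue
        cr = rng.uniform(margin, h - 1 - margin)
        cc = rng.uniform(margin, w - 1 - margin)
        ok = all(
            np.hypot(cr - c["center"][0], cc - c["center"][1])
            > r_cell_px + c["r_cell_px"] + 2.0
            for c in cells
        )
        if ok:
            cells.append(
                {
                    "center": (cr, cc),
                    "a_px": a,
                    "b_px": b,
                    "theta": theta,
                    "r_cell_px": r_cell_px,
                }
            )
    return cells


def _gap_arcs(
    gap_fraction: float, rng: np.random.Generator, min_arc: float = 0.25
) -> list[tuple[float, float]]:
    """1–3 disjoint angular arcs (start, end) totalling gap_fraction·2π.

    Every gap arc and every intervening rim segment is at least ``min_arc``
    radians long (when the fractions allow it), so planted gap and fragment
    counts survive pixel quantization and are exactly recoverable.
    """
    if gap_fraction <= 0:
        return []
    if gap_fraction >= 1:
        return [(0.0, 2 * np.pi)]
    total_gap = gap_fraction * 2 * np.pi
    total_rim = 2 * np.pi - total_gap
    n_max = min(3, int(total_gap // min_arc), int(total_rim // min_arc))
    n = int(rng.integers(1, 4))
    n = max(1, min(n, n_max))

    def _parts(total: float, m: int) -> np.ndarray:
        if total <= m * min_arc:
            return np.full(m, total / m)
        return min_arc + rng.dirichlet(np.ones(m)) * (total - m * min_arc)

    gap_parts = _parts(total_gap, n)
    rim_parts = _parts(total_rim, n)
    cursor = rng.uniform(0, 2 * np.pi)
    arcs = []
    for gp, rp in zip(gap_parts, rim_parts):
        arcs.append((cursor, cursor + gp))
        cursor += gp + rp
    return arcs


def _in_arcs(angles: np.ndarray, arcs: list[tuple[float, float]]) -> np.ndarray:
    out = np.zeros(angles.shape, dtype=bool)
    tw = 2 * np.pi
    for s, e in arcs:
        out |= ((angles - s) % tw) <= (e - s)
    return out


def _place_puncta(
    cyto: np.ndarray, n: int, r_px: int, rng: np.random.Generator
) -> np.ndarray:
    """Centroids (k, 2) of non-overlapping puncta fully inside the cytosol."""
    # erode so a disk of radius r_px around the centre stays inside the cytosol
    allowed = ndimage.binary_erosion(cyto, structure=disk_footprint(r_px + 1))
    coords = np.argwhere(allowed)
    if len(coords) == 0 and n > 0:
        raise RuntimeError(
            f"cytosol too thin to host puncta of radius {r_px} px; "
            "enlarge the cell radius or shrink the puncta"
        )
    chosen: list[np.ndarray] = []
    tries = 0
    while len(chosen) < n:
        tries += 1
        if tries > 200 * n:
            raise RuntimeError(
                f"could not place {n} non-overlapping puncta of radius {r_px} px "
                "in one cytosol; reduce n_puncta or punctum_radius_um"
            )
        cand = coords[rng.integers(len(coords))]
        if all(np.hypot(*(cand - c)) > 2 * r_px + 2 for c in chosen):
            chosen.append(cand)
    return np.array(chosen, dtype=int).reshape(-1, 2)


def generate_scene(spec: SceneSpec) -> tuple[dict[str, ChannelImage], GroundTruth]:
    """Rasterize a scene and return its channels plus full ground truth.

    Returns one :class:`ChannelImage` per marker, plus a DNA (nuclear stain)
    channel under the key ``"DNA"``. Identical seeds give bit-identical
    output.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_shape
    geoms = _place_cells(spec, rng)

    nucleus_labels = np.zeros((h, w), dtype=np.int32)
    cell_labels = np.zeros((h, w), dtype=np.int32)
    for i, g in enumerate(geoms, start=1):
        nuc = _rasterize_ellipse((h, w), g["center"], g["a_px"], g["b_px"], g["theta"])
        cell = _rasterize_ellipse(
            (h, w), g["center"], g["r_cell_px"], g["r_cell_px"], 0.0
        )
        cell |= nuc
        nucleus_labels[nuc] = i
        cell_labels[cell] = i
        g["cell_id"] = i

    clean: dict[str, np.ndarray] = {}
    structure_masks: dict[str, np.ndarray] = {}
    ring_signal: dict[str, np.ndarray] = {}
    ring_band: dict[str, np.ndarray] = {}
    puncta_centroids: dict[str, dict[int, np.ndarray]] = {}
    overlap_fraction: dict[str, float] = {}
    per_cell_extra: dict[str, dict[int, dict]] = {}

    dna = np.full((h, w), spec.background_level, dtype=np.float64)
    dna[nucleus_labels > 0] += spec.dna_level
    clean[DNA_CHANNEL] = dna

    for m in spec.markers:
        img = np.full((h, w), spec.background_level, dtype=np.float64)
        if m.overlap_with is not None:
            other, frac = m.overlap_with
            if other not in structure_masks:
                raise ValueError(
                    f"marker '{m.name}' declares overlap with '{other}', which must "
                    "be generated earlier in the marker list"
                )
            ref = structure_masks[other]
            n_ref = int(ref.sum())
            if n_ref == 0:
                raise ValueError(f"overlap reference channel '{other}' has no foreground")
            n_ov = int(round(frac * n_ref))
            ref_idx = np.flatnonzero(ref.ravel())
            fg = np.zeros(h * w, dtype=bool)
            fg[ref_idx[:n_ov]] = True
            # disjoint filler so the channel has foreground even at frac = 0
            filler_pool = np.flatnonzero(~ref.ravel())
            fg[filler_pool[: max(200, n_ov // 4)]] = True
            fg = fg.reshape(h, w)
            level = m.cytosol_level if m.cytosol_level > 0 else 200.0
            img[fg] += level
            structure_masks[m.name] = fg
            overlap_fraction[m.name] = n_ov / n_ref
            clean[m.name] = img
            continue

        band_all = np.zeros((h, w), dtype=bool)
        signal_all = np.zeros((h, w), dtype=bool)
        puncta_centroids[m.name] = {}
        per_cell_extra.setdefault(m.name, {})
        ring_w_px = um_to_px(m.ring_width_um, spec.pixel_size) if m.ring_level > 0 else 0
        r_punct_px = um_to_px(m.punctum_radius_um, spec.pixel_size) if m.n_puncta else 0

        for g in geoms:
            cid = g["cell_id"]
            nuc = nucleus_labels == cid
            cell = cell_labels == cid
            cyto = cell & ~nuc
            img[nuc] += m.nucleus_level
            img[cyto] += m.cytosol_level

            gap_arcs: list[tuple[float, float]] = []
            if m.ring_level > 0 and ring_w_px >= 1:
                band = ndimage.binary_dilation(nuc, structure=disk_footprint(ring_w_px)) & ~nuc
                gap_arcs = _gap_arcs(m.gap_fraction, rng)
                rr, cc = np.nonzero(band)
                ang = np.arctan2(rr - g["center"][0], cc - g["center"][1]) % (2 * np.pi)
                gap_px = np.zeros(band.shape, dtype=bool)
                gap_px[rr, cc] = _in_arcs(ang, gap_arcs)
                sig = band & ~gap_px
                img[sig] += m.ring_level
                band_all |= band
                signal_all |= sig

            if m.n_puncta > 0 and r_punct_px >= 1:
                cents = _place_puncta(cyto, m.n_puncta, r_punct_px, rng)
                for cr, cc_ in cents:
                    pm = _rasterize_ellipse((h, w), (cr, cc_), r_punct_px, r_punct_px, 0.0)
                    img[pm] += m.punctum_level
                puncta_centroids[m.name][cid] = cents
            else:
                puncta_centroids[m.name][cid] = np.zeros((0, 2), dtype=int)

            per_cell_extra[m.name][cid] = {
                "gap_fraction": m.gap_fraction if m.ring_level > 0 else np.nan,
                "n_gaps": len(gap_arcs),
                "n_puncta": m.n_puncta if m.n_puncta > 0 else 0,
            }

        ring_signal[m.name] = signal_all
        ring_band[m.name] = band_all
        structure_masks[m.name] = img > spec.background_level
        clean[m.name] = img

    # per-cell ground-truth table
    rows = []
    for g in geoms:
        row = {
            "cell_id": g["cell_id"],
            "center_row": g["center"][0],
            "center_col": g["center"][1],
            "nucleus_a_px": g["a_px"],
            "nucleus_b_px": g["b_px"],
            "theta": g["theta"],
            "cell_radius_px": g["r_cell_px"],
        }
        for m in spec.markers:
            if m.overlap_with is not None:
                continue
            row[f"{m.name}_true_cn"] = m.true_cn if m.true_cn is not None else np.nan
            extra = per_cell_extra[m.name][g["cell_id"]]
            row[f"{m.name}_gap_fraction"] = extra["gap_fraction"]
            row[f"{m.name}_n_gaps"] = extra["n_gaps"]
            row[f"{m.name}_n_puncta"] = extra["n_puncta"]
        rows.append(row)
    cells_df = pd.DataFrame(rows)

    # noise, applied channel-wise after rasterization
    channels: dict[str, ChannelImage] = {}
    for name, img in clean.items():
        noisy = img
        if spec.poisson:
            noisy = rng.poisson(noisy).astype(np.float64)
        if spec.gaussian_sd > 0:
            noisy = noisy + rng.normal(0.0, spec.gaussian_sd, size=noisy.shape)
        noisy = np.clip(noisy, 0.0, None)
        channels[name] = ChannelImage(noisy, spec.pixel_size, channel_name=name)

    gt = GroundTruth(
        nucleus_labels=nucleus_labels,
        cell_labels=cell_labels,
        cells=cells_df,
        ring_signal_masks=ring_signal,
        ring_band_masks=ring_band,
        structure_masks=structure_masks,
        puncta_centroids=puncta_centroids,
        overlap_fraction=overlap_fraction,
    )
    return channels, gt


def generate_cohort(design: CohortDesign) -> pd.DataFrame:
    """Simulate a clustered measurement table.

    Returns a tidy frame with columns ``group``, ``cluster_id``,
    ``experiment_id``, ``cell_id``, ``metric``, ``value`` — one row per
    cell, ``groups × clusters_per_group × cells_per_cluster`` rows in
    total. Cluster ids are unique across groups.
    """
    rng = np.random.default_rng(design.seed)
    rows = []
    for gi, eff in enumerate(design.group_effects):
        for ci in range(design.clusters_per_group):
            intercept = rng.normal(0.0, design.cluster_sd) if design.cluster_sd > 0 else 0.0
            resid = rng.normal(0.0, design.cell_sd, size=design.cells_per_cluster)
            vals = eff + intercept + resid
            if design.distribution == "lognormal":
                vals = np.exp(vals)
            cluster = f"g{gi}_c{ci}"
            for k, v in enumerate(vals):
                rows.append(
                    {
                        "group": f"group{gi}",
                        "cluster_id": cluster,
                        "experiment_id": cluster,
                        "cell_id": k,
                        "metric": "synthetic",
                        "value": v,
                    }
                )
    return pd.DataFrame(rows)
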