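"""End-to-end orchestration: images → per-cell metrics → clustered rank tests.

Mirrors the figure workflow of the study design: quantify each cell, pool
per-cell values into a tidy measurement table, optionally normalise to the
control condition within each experiment, then test group differences with
the cluster-robust rank procedures. Fully deterministic for fixed inputs,
config and seed; every excluded cell is logged with its reason.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import metrics as M
from . import segment as S
from .config import RunConfig
from .image import ChannelImage
from .io import SampleSheet, read_image
from .stats import (
    StatTestResult,
    cluster_robust_rank_anova,
    cluster_robust_rank_ttest,
    significance_stars,
)

__all__ = ["quantify_image", "run_pipeline", "write_report", "KNOWN_METRICS"]

logger = logging.getLogger(__name__)

KNOWN_METRICS = (
    "cn_ratio",
    "nc_gradient",
    "laminar_intensity",
    "envelope_nucleoplasm_ratio",
    "continuity_index",
    "circularity",
    "puncta_count",
)


def _puncta_threshold(image: ChannelImage, background: float, config: RunConfig) -> float:
    if config.puncta_threshold is not None:
        return config.puncta_threshold
    span = float(np.percentile(image.pixels, 99.5)) - background
    return background + 0.5 * span


def quantify_image(
    channels: dict[str, ChannelImage],
    config: RunConfig,
    metric_names: list[str],
    dna_channel: str = "DNA",
    cell_channel: str | None = None,
    marker_channel: str | None = None,
) -> tuple[pd.DataFrame, list[str]]:
    """Quantify one multi-channel image.

    ``cell_channel`` defines the cytosolic boundary (defaults to the marker
    channel); ``marker_channel`` is the channel being measured (defaults to
    the first non-DNA channel). Returns (per-cell tidy rows, exclusion log).
    """
    unknown = set(metric_names) - set(KNOWN_METRICS)
    if unknown:
        raise ValueError(f"unknown metrics: {sorted(unknown)}; known: {KNOWN_METRICS}")
    if dna_channel not in channels:
        raise ValueError(f"DNA channel '{dna_channel}' not among {list(channels)}")
    non_dna = [n for n in channels if n != dna_channel]
    if not non_dna:
        raise ValueError("need at least one marker channel besides the DNA stain")
    marker_channel = marker_channel or non_dna[0]
    cell_channel = cell_channel or marker_channel
    marker = channels[marker_channel]
    dna = channels[dna_channel]

    nuclei = S.segment_nuclei(
        dna,
        config.min_nucleus_area_um2,
        method=config.threshold_method,
        threshold_value=config.threshold_value,
    )
    if not nuclei:
        return pd.DataFrame(), ["no nuclei found"]
    cells = S.segment_cells(channels[cell_channel], nuclei)

    if config.background_value is not None:
        background = config.background_value
    else:
        background, _ = S.estimate_background(
            marker, [c.cell_mask for c in cells], guard_px=config.background_guard_px
        )

    rows: list[dict] = []
    excluded: list[str] = []
    for cell in cells:
        ring = None
        if {"laminar_intensity", "continuity_index"} & set(metric_names):
            ring = S.make_ring(
                cell.nucleus_mask,
                config.laminar_outer_um,
                config.laminar_inner_um,
                marker.pixel_size,
            )
        for name in metric_names:
            try:
                if name == "cn_ratio":
                    value = M.cn_ratio(marker, cell, background)
                elif name == "nc_gradient":
                    value = M.nc_gradient(marker, cell, background)
                elif name == "laminar_intensity":
                    value = M.laminar_intensity(marker, ring, background)
                elif name == "envelope_nucleoplasm_ratio":
                    value = M.envelope_to_nucleoplasm_ratio(
                        marker, cell.nucleus_mask, band_px=config.envelope_band_px
                    )
                elif name == "continuity_index":
                    profile = M.envelope_profile(
                        marker, cell.nucleus_mask, config.continuity_ring_width_um
                    )
                    thr = (
                        config.continuity_threshold
                        if config.continuity_threshold is not None
                        else M.default_continuity_threshold(profile, background=background)
                    )
                    value, _, _ = M.continuity_index(profile, thr)
                elif name == "circularity":
                    value = M.circularity(cell.nucleus_mask, marker.pixel_size)
                elif name == "puncta_count":
                    thr = _puncta_threshold(marker, background, config)
                    pset = M.detect_puncta(
                        marker,
                        cell.cytosol_mask,
                        thr,
                        config.puncta_min_area_um2,
                        config.puncta_max_area_um2,
                    )
                    value = float(len(pset))
                rows.append(
                    {
                        "cell_id": cell.cell_id,
                        "metric": name,
                        "value": float(value),
                        "background": background,
                    }
                )
            except M.UndefinedMetric as exc:
                excluded.append(f"cell {cell.cell_id}, {name}: {exc}")
                logger.info("excluded cell %s for %s: %s", cell.cell_id, name, exc)
    return pd.DataFrame(rows), excluded


def run_pipeline(
    sheet: SampleSheet,
    config: RunConfig,
    metric_names: list[str],
    dna_channel: str = "DNA",
    cell_channel: str | None = None,
    marker_channel: str | None = None,
    out_dir: str | Path | None = None,
) -> tuple[pd.DataFrame, dict[str, StatTestResult], str]:
    """Quantify every sheet row, normalise, test, and (optionally) write.

    Returns ``(measurements, {metric: StatTestResult}, report)``. With
    ``out_dir`` set, writes ``measurements.csv``, ``stats.csv``,
    ``report.txt``, ``exclusions.log`` and the effective ``config.yaml``.
    """
    all_rows = []
    all_excluded: list[str] = []
    for idx, row in sheet.table.iterrows():
        path = sheet.paths()[idx]
        channels = read_image(path, channel_names=sheet.channel_names(row))
        per_cell, excluded = quantify_image(
            channels,
            config,
            metric_names,
            dna_channel=dna_channel,
            cell_channel=cell_channel,
            marker_channel=marker_channel,
        )
        all_excluded += [f"{path.name}: {e}" for e in excluded]
        if per_cell.empty:
            continue
        per_cell.insert(0, "image_id", path.name)
        per_cell["group"] = row["group"]
        per_cell["cluster_id"] = row["cluster_id"]
        per_cell["experiment_id"] = row["experiment_id"]
        all_rows.append(per_cell)
    if not all_rows:
        raise ValueError("pipeline produced no measurements")
    measurements = pd.concat(all_rows, ignore_index=True)

    if config.control_group is not None:
        normalised = []
        for metric, sub in measurements.groupby("metric", sort=False):
            normalised.append(
                M.normalize_to_control(sub, config.control_group)
            )
        measurements = pd.concat(normalised).sort_index()

    results: dict[str, StatTestResult] = {}
    for metric, sub in measurements.groupby("metric", sort=False):
        n_groups = sub["group"].nunique()
        if n_groups < 2:
            logger.warning("metric %s: only one group, skipping test", metric)
            continue
        if n_groups == 2:
            res = cluster_robust_rank_ttest(
                sub, alpha=config.alpha, estimator=config.variance_estimator
            )
        else:
            res = cluster_robust_rank_anova(
                sub,
                alpha=config.alpha,
                estimator=config.variance_estimator,
                adjust=config.adjustment,
            )
        results[metric] = res

    report = write_report(measurements, results)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        _atomic_csv(measurements, out / "measurements.csv")
        stats_rows = []
        for metric, res in results.items():
            stats_rows.append(
                {
                    "metric": metric,
                    "contrast": "omnibus",
                    "estimate": np.nan,
                    "se": np.nan,
                    "df": res.omnibus_df[1],
                    "stat": res.omnibus_stat,
                    "p_raw": res.omnibus_p,
                    "p_adj": res.omnibus_p,
                }
            )
            for _, c in res.contrasts.iterrows():
                stats_rows.append(
                    {
                        "metric": metric,
                        "contrast": f"{c['group_a']} vs {c['group_b']}",
                        "estimate": c["estimate"],
                        "se": c["se"],
                        "df": c["df"],
                        "stat": c["t"],
                        "p_raw": c["p_raw"],
                        "p_adj": c["p_adj"],
                    }
                )
        _atomic_csv(pd.DataFrame(stats_rows), out / "stats.csv")
        (out / "report.txt").write_text(report)
        (out / "exclusions.log").write_text("\n".join(all_excluded) + "\n")
        config.to_yaml(out / "config.yaml")
    return measurements, results, report


def _atomic_csv(df: pd.DataFrame, path: Path) -> None:
    tmp = path.with_suffix(path.suffix + ".tmp")
    df.to_csv(tmp, index=False, float_format="%.10g")
    tmp.replace(path)


def write_report(
    measurements: pd.DataFrame, results: dict[str, StatTestResult]
) -> str:
    """Human-readable summary: per-group distribution stats plus tests.

    Distributions are reported the way the source figures draw them:
    quartiles (boxes), median (center line), and the 10–90 percentile range
    (whiskers), with the usual significance ladder.
    """
    if measurements.empty:
        return "no measurements\n"
    lines = ["# Measurement summary", ""]
    for metric, sub in measurements.groupby("metric", sort=False):
        lines.append(f"## {metric}")
        for group, gsub in sub.groupby("group", sort=False):
            v = gsub["value"].to_numpy()
            q10, q25, q50, q75, q90 = np.percentile(v, [10, 25, 50, 75, 90])
            lines.append(
                f"  {group}: n={len(v)}, median={q50:.4g}, "
                f"quartiles=[{q25:.4g}, {q75:.4g}], range10-90=[{q10:.4g}, {q90:.4g}]"
            )
        res = results.get(metric)
        if res is not None:
            lines.append(
                f"  omnibus p={res.omnibus_p:.4g} {significance_stars(res.omnibus_p)}"
            )
            for _, c in res.contrasts.iterrows():
                lines.append(
                    f"  {c['group_a']} vs {c['group_b']}: p_adj={c['p_adj']:.4g} "
                    f"{significance_stars(c['p_adj'])}"
                )
        lines.append("")
    return "\n".join(lines)
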