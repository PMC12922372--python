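"""OME-TIFF and tabular I/O.

Scenes travel as one OME-TIFF per image (channels as planes, physical pixel
size in the metadata); everything tabular — sample sheets, ground truth,
measurement tables, test results — is plain CSV. Pixel size resolution
order: explicit override (with a logged warning if metadata disagrees),
else OME metadata, else an error — never a silent default.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .image import ChannelImage

__all__ = ["write_ome_tiff", "read_image", "read_sample_sheet", "SampleSheet"]

logger = logging.getLogger(__name__)


def write_ome_tiff(
    path: str | Path, channels: dict[str, ChannelImage]
) -> None:
    """Write named channels as one OME-TIFF with pixel size metadata."""
    if not channels:
        raise ValueError("no channels to write")
    names = list(channels)
    px = {c.pixel_size for c in channels.values()}
    if len(px) != 1:
        raise ValueError("all channels must share one pixel size")
    pixel_size = px.pop()
    stack = np.stack([channels[n].pixels for n in names]).astype(np.float32)
    tifffile.imwrite(
        str(path),
        stack,
        ome=True,
        metadata={
            "axes": "CYX",
            "Channel": {"Name": names},
            "PhysicalSizeX": pixel_size,
            "PhysicalSizeXUnit": "µm",
            "PhysicalSizeY": pixel_size,
            "PhysicalSizeYUnit": "µm",
        },
    )


def _pixel_size_from_ome(tf: tifffile.TiffFile) -> float | None:
    try:
        import xml.etree.ElementTree as ET

        root = ET.fromstring(tf.ome_metadata)
        for el in root.iter():
            if el.tag.endswith("Pixels"):
                v = el.attrib.get("PhysicalSizeX")
                if v is not None:
                    return float(v)
    except Exception:
        return None
    return None


def _channel_names_from_ome(tf: tifffile.TiffFile, n: int) -> list[str]:
    try:
        import xml.etree.ElementTree as ET

        root = ET.fromstring(tf.ome_metadata)
        names = [
            el.attrib.get("Name")
            for el in root.iter()
            if el.tag.endswith("Channel")
        ]
        names = [x for x in names if x]
        if len(names) == n:
            return names
    except Exception:
        pass
    return [f"ch{i}" for i in range(n)]


def read_image(
    path: str | Path,
    pixel_size_override: float | None = None,
    channel_names: list[str] | None = None,
) -> dict[str, ChannelImage]:
    """Read a (OME-)TIFF into named ChannelImages.

    ``channel_names``, when given (e.g. from the sample sheet), takes
    precedence over metadata names. Missing pixel size with no override is
    an error.
    """
    with tifffile.TiffFile(str(path)) as tf:
        arr = tf.asarray()
        meta_px = _pixel_size_from_ome(tf) if tf.ome_metadata else None
        if arr.ndim == 2:
            arr = arr[None]
        if arr.ndim != 3:
            raise ValueError(f"{path}: expected 2-D or (C, Y, X) data, got {arr.shape}")
        names = channel_names or _channel_names_from_ome(tf, arr.shape[0])
    if len(names) != arr.shape[0]:
        raise ValueError(
            f"{path}: {arr.shape[0]} planes but {len(names)} channel names"
        )
    if pixel_size_override is not None:
        if meta_px is not None and not np.isclose(meta_px, pixel_size_override):
            logger.warning(
                "%s: pixel-size override %.4g µm/px differs from metadata %.4g; "
                "using the override",
                path,
                pixel_size_override,
                meta_px,
            )
        pixel_size = pixel_size_override
    elif meta_px is not None:
        pixel_size = meta_px
    else:
        raise ValueError(
            f"{path}: no pixel size in metadata; pass an explicit pixel size"
        )
    return {
        n: ChannelImage(arr[i].astype(np.float64), pixel_size, channel_name=n)
        for i, n in enumerate(names)
    }


class SampleSheet:
    """Image → (group, cluster, experiment, channel names) mapping.

    CSV columns: ``image`` (path), ``group``, ``cluster_id``,
    ``experiment_id``, ``channels`` (comma- or semicolon-separated channel
    names in plane order; optional when the TIFF carries OME channel names).
    """

    REQUIRED = ("image", "group", "cluster_id", "experiment_id")

    def __init__(self, table: pd.DataFrame, base_dir: Path | None = None):
        missing = [c for c in self.REQUIRED if c not in table.columns]
        if missing:
            raise ValueError(f"sample sheet missing columns: {missing}")
        if table.empty:
            raise ValueError("sample sheet is empty")
        for col in self.REQUIRED[1:]:
            if table[col].isna().any() or (table[col].astype(str) == "").any():
                raise ValueError(f"sample sheet column '{col}' has empty entries")
        self.table = table.reset_index(drop=True)
        self.base_dir = base_dir or Path(".")
        for p in self.paths():
            if not p.exists():
                raise FileNotFoundError(f"sample sheet references missing image {p}")

    @classmethod
    def from_csv(cls, path: str | Path) -> "SampleSheet":
        path = Path(path)
        return cls(pd.read_csv(path), base_dir=path.parent)

    def paths(self) -> list[Path]:
        return [
            p if (p := Path(str(v))).is_absolute() else self.base_dir / p
            for v in self.table["image"]
        ]

    def channel_names(self, row: pd.Series) -> list[str] | None:
        raw = row.get("channels")
        if raw is None or (isinstance(raw, float) and np.isnan(raw)):
            return None
        return [s.strip() for s in str(raw).replace(";", ",").split(",") if s.strip()]

    def __len__(self) -> int:
        return len(self.table)
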