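"""Run configuration: every tunable in one flat, file-round-trippable record."""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields
from pathlib import Path

import yaml

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """All pipeline tunables with their defaults.

    Units are µm for physical lengths and µm² for areas. ``None`` means
    "derive automatically" where a rule exists (continuity threshold,
    puncta threshold).
    """

    # segmentation
    threshold_method: str = "otsu"          # otsu | fixed | percentile
    threshold_value: float | None = None
    min_nucleus_area_um2: float = 10.0
    background_guard_px: int = 2
    background_value: float | None = None   # overrides estimation when set

    # rings / bands
    laminar_inner_um: float = 0.0
    laminar_outer_um: float = 1.3
    envelope_band_px: int = 1
    perinuclear_width_um: float = 1.5

    # puncta
    puncta_threshold: float | None = None   # None: background + half Otsu span
    puncta_min_area_um2: float = 0.1
    puncta_max_area_um2: float = 5.0
    puncta_min_roundness: float = 0.6
    puncta_max_dist_to_envelope_um: float = 2.0

    # continuity
    continuity_threshold: float | None = None  # None: half-way rule
    continuity_ring_width_um: float = 1.3

    # statistics
    variance_estimator: str = "CR2"         # CR2 | CR1 | CR0
    adjustment: str = "tukey"               # tukey | holm | none
    alpha: float = 0.05
    control_group: str | None = None        # enables per-experiment normalisation

    seed: int = 0

    def __post_init__(self) -> None:
        if self.threshold_method not in ("otsu", "fixed", "percentile"):
            raise ValueError(f"unknown threshold_method '{self.threshold_method}'")
        if self.variance_estimator not in ("CR2", "CR1", "CR0"):
            raise ValueError(f"unknown variance_estimator '{self.variance_estimator}'")
        if self.adjustment not in ("tukey", "holm", "none"):
            raise ValueError(f"unknown adjustment '{self.adjustment}'")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        """Load from a flat YAML mapping; unknown keys are an error."""
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def to_dict(self) -> dict:
        return asdict(self)
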