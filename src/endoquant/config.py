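"""Run configuration: the constants of the analysis workflow.

The defaults are the reference workflow's printed parameters (rolling-ball
radii 300/80/25 px, orientation window sigma 4 px, ROI margin 3 um, blur
sigma 2 px, ten-degree bins, perinuclear ring 2 um).  ``pixel_size_um`` has
no default: the acquisitions' pixel sizes are not published, so it is a
required input.  Every CLI run serializes its resolved configuration next
to its outputs for provenance.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import yaml

__all__ = ["AnalysisConfig"]

CONFIG_SCHEMA_VERSION = 1


@dataclass
class AnalysisConfig:
    pixel_size_um: float | None = None
    frame_interval_min: float | None = None
    aj_rolling_radius_px: int = 300
    channel_rolling_radius_px: int = 80
    yap_rolling_radius_px: int = 25
    yap_fixed_threshold: float | None = None
    orientation_window_sigma_px: float = 4.0
    mismatch_margin_um: float = 3.0
    blur_sigma_px: float = 2.0
    bin_width_deg: float = 10.0
    ring_width_um: float = 2.0
    positivity_threshold: float | None = None
    leak_fixed_threshold: float | None = None
    seed: int = 0
    schema_version: int = CONFIG_SCHEMA_VERSION

    def require(self, *names: str) -> None:
        """Fail fast when a required field was not supplied."""
        missing = [n for n in names if getattr(self, n) is None]
        if missing:
            raise ValueError(
                "missing required configuration field(s): " + ", ".join(missing)
            )
        self.validate()

    def validate(self) -> None:
        errors = []
        positive = {
            "pixel_size_um": self.pixel_size_um,
            "frame_interval_min": self.frame_interval_min,
            "orientation_window_sigma_px": self.orientation_window_sigma_px,
            "mismatch_margin_um": self.mismatch_margin_um,
            "blur_sigma_px": self.blur_sigma_px,
            "bin_width_deg": self.bin_width_deg,
            "ring_width_um": self.ring_width_um,
        }
        for name, val in positive.items():
            if val is not None and val <= 0:
                errors.append(f"{name} must be positive (got {val})")
        for name in (
            "aj_rolling_radius_px",
            "channel_rolling_radius_px",
            "yap_rolling_radius_px",
        ):
            if getattr(self, name) < 1:
                errors.append(f"{name} must be >= 1")
        if errors:
            raise ValueError("invalid configuration: " + "; ".join(errors))

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "AnalysisConfig":
        """Load a YAML config; keyword overrides (CLI flags) win."""
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown configuration field(s): {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def dump(self, path: str | Path) -> None:
        """Serialize the resolved configuration (JSON) for provenance."""
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")
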