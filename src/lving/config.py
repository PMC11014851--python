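"""Pipeline configuration: every tunable knob, with units in key names.

Unit bugs are the dominant failure mode for this kind of tool, so every
physical key carries its unit in its name and unknown keys are rejected at
load time.  Config files may be YAML (.yaml/.yml) or TOML (.toml).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import tomllib
from dataclasses import dataclass
from pathlib import Path

import yaml

from .mass_imaging import Calibration
from .velocimetry import PIVConfig

__all__ = ["PipelineConfig", "load_config"]


@dataclass(frozen=True)
class PipelineConfig:
    """Validated pipeline settings.

    Calibration keys are optional; when omitted the OPD stack's metadata
    sidecar supplies them.
    """

    # calibration (override the sidecar when set)
    pixel_size_um: float | None = None
    frame_interval_min: float | None = None
    refractive_increment: float = 0.18
    # velocimetry
    window_size_px: int = 32
    window_overlap: float = 0.75
    search_radius_px: int = 4
    min_density_pg_per_um2: float = 0.05
    outlier_zmax: float = 3.0
    peak_quality_min: float = 1.2
    smooth_sigma_nodes: float = 1.0
    # control volumes / growth windows
    cv_area_um2: float = 0.7
    window_min: float = 30.0
    step_min: float | None = None
    advection_scheme: str = "euler"
    integration_method: str = "clip"
    # segmentation & puncta
    segmentation_threshold_pg_per_um2: float = 0.05
    puncta_threshold_pg_per_h: float | None = None  # None -> robust MAD default
    puncta_min_area_um2: float = 0.5
    # reproducibility
    seed: int = 0

    def __post_init__(self) -> None:
        positive = {
            "refractive_increment": self.refractive_increment,
            "cv_area_um2": self.cv_area_um2,
            "window_min": self.window_min,
            "segmentation_threshold_pg_per_um2": self.segmentation_threshold_pg_per_um2,
            "puncta_min_area_um2": self.puncta_min_area_um2,
        }
        for name, value in positive.items():
            if value <= 0:
                raise ValueError(f"{name} must be strictly positive")
        for name in ("pixel_size_um", "frame_interval_min", "step_min"):
            value = getattr(self, name)
            if value is not None and value <= 0:
                raise ValueError(f"{name} must be strictly positive when given")
        if self.advection_scheme not in {"euler", "rk2"}:
            raise ValueError("advection_scheme must be 'euler' or 'rk2'")
        if self.integration_method not in {"clip", "supersample"}:
            raise ValueError("integration_method must be 'clip' or 'supersample'")
        self.piv_config()  # validates the PIV keys

    def piv_config(self) -> PIVConfig:
        return PIVConfig(
            window_size=self.window_size_px,
            window_overlap=self.window_overlap,
            search_radius=self.search_radius_px,
            min_density=self.min_density_pg_per_um2,
            outlier_zmax=self.outlier_zmax,
            peak_quality_min=self.peak_quality_min,
            smooth_sigma_nodes=self.smooth_sigma_nodes,
        )

    def calibration(self, fallback: Calibration | None = None) -> Calibration:
        """Calibration from config keys, falling back to the sidecar's."""
        if self.pixel_size_um is not None and self.frame_interval_min is not None:
            return Calibration(
                self.pixel_size_um, self.frame_interval_min, self.refractive_increment
            )
        if fallback is None:
            raise ValueError(
                "pixel_size_um and frame_interval_min must come from the config "
                "or a metadata sidecar"
            )
        return Calibration(
            fallback.pixel_size, fallback.frame_interval, self.refractive_increment
        )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def content_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


def load_config(path: str | Path) -> PipelineConfig:
    """Load and validate a YAML or TOML config; unknown keys are an error."""
    path = Path(path)
    if path.suffix == ".toml":
        data = tomllib.loads(path.read_text())
    else:
        data = yaml.safe_load(path.read_text()) or {}
    if not isinstance(data, dict):
        raise ValueError(f"config {path.name} must be a mapping")
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(
            f"unknown config key(s) {sorted(unknown)}; known keys: {sorted(known)}"
        )
    return PipelineConfig(**data)
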