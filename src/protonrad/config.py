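"""Run configuration: schema-validated defaults for the whole pipeline.

Defaults mirror the reference beamline setup (0.05 mm detector pitch,
8.4 Hz frame rate, 256 px damage-map tiles, maxima prominences 600/1400)
and are overridable from a JSON file.  Dose rates are geometry-specific
calibration constants and therefore live in a named registry rather than
in code.
"""

from __future__ import annotations

import json
from pathlib import Path

from pydantic import BaseModel, Field, field_validator

__all__ = ["RunConfig", "load_config"]


class RunConfig(BaseModel):
    """Validated pipeline configuration."""

    pixel_pitch_mm: float = Field(0.05, gt=0)
    frame_rate_hz: float = Field(8.4, gt=0)
    # mGy/s at the object position; calibration per named geometry
    dose_rates_mGy_per_s: dict[str, float] = {
        "grid-phantom-200MeV-0.1nA": 1.98,
        "mouse-position-200MeV-0.1nA": 2.875,
    }
    default_geometry: str = "mouse-position-200MeV-0.1nA"
    axis_convention: str = "detector-default"
    prominence_dapi: float = Field(600.0, gt=0)
    prominence_gh2ax: float = Field(1400.0, gt=0)
    tile_px: int = Field(256, gt=0)
    min_cells_per_tile: int = Field(5, ge=0)
    cnr_detect_threshold: float = Field(4.0, gt=0)
    qa_tolerance_mm: float = Field(0.5, gt=0)

    @field_validator("dose_rates_mGy_per_s")
    @classmethod
    def _rates_positive(cls, v: dict[str, float]) -> dict[str, float]:
        if any(rate < 0 for rate in v.values()):
            raise ValueError("dose rates must be non-negative")
        return v

    def dose_rate(self, geometry: str | None = None) -> float:
        name = geometry or self.default_geometry
        if name not in self.dose_rates_mGy_per_s:
            raise KeyError(
                f"no dose-rate calibration for geometry {name!r}; "
                f"known: {sorted(self.dose_rates_mGy_per_s)}"
            )
        return self.dose_rates_mGy_per_s[name]


def load_config(path: str | Path | None = None) -> RunConfig:
    """Load (and validate) a JSON config; defaults when path is None."""
    if path is None:
        return RunConfig()
    return RunConfig.model_validate(json.loads(Path(path).read_text()))
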