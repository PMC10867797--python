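"""Run configuration and simulation design files (YAML)."""

from __future__ import annotations

from pathlib import Path
from typing import Literal, Optional, Union

import yaml
from pydantic import BaseModel, Field, ValidationError, model_validator

from .quant import CorrectionMode, Weighting
from .simulate import GroundTruthSample, PeakShapeParams


class SampleDesign(BaseModel):
    """One non-calibrant sample in a simulation design.

    Either explicit per-channel ``concentrations`` or a labeling design
    (``totals`` + per-analyte isotopologue ``fractions`` summing to 1).
    """

    sample_id: str
    role: Literal["blank", "sample", "spiked_sample"] = "sample"
    concentrations: dict[str, dict[int, float]] = Field(default_factory=dict)
    totals: dict[str, float] = Field(default_factory=dict)
    fractions: dict[str, dict[int, float]] = Field(default_factory=dict)
    matrix_factor: float = 1.0

    @model_validator(mode="after")
    def _one_spec(self) -> "SampleDesign":
        if self.fractions and set(self.fractions) != set(self.totals):
            raise ValueError(
                f"{self.sample_id}: fractions and totals must name the same analytes"
            )
        return self


class RunConfig(BaseModel):
    """Complete, seedable description of a simulate→quantify run."""

    seed: int = 0
    panel_path: Optional[str] = None
    n_calibration_levels: int = Field(ge=2, default=6)
    n_blanks: int = Field(ge=0, default=4)
    window_half_width: float = Field(gt=0, default=0.5)
    labeled_analytes: list[str] = Field(default_factory=list)
    weighting: Weighting = "1/x"
    correction_mode: CorrectionMode = "cascade"
    background_correction: bool = True
    shape: dict = Field(default_factory=dict)  # PeakShapeParams overrides
    samples: list[SampleDesign] = Field(default_factory=list)


class ConfigError(ValueError):
    pass


def load_config(path: Union[str, Path]) -> RunConfig:
    try:
        doc = yaml.safe_load(Path(path).read_text())
        return RunConfig(**(doc or {}))
    except ValidationError as exc:
        raise ConfigError(f"{path}: {exc}") from exc
    except yaml.YAMLError as exc:
        raise ConfigError(f"{path}: invalid YAML: {exc}") from exc
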