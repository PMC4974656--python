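"""Pipeline configuration: schema-validated, defaulting to the study's
printed constants (60x34 cm screen at 20 cm, 4 Hz Hartley updates capped
at 0.15 cpd, 15.5 Hz imaging, tau_1/2 = 135 ms with a 10-knot drift
spline, fivefold CV, r_L >= 0.15 with > 20 cells per field, 30-um distance
bins to 210 um and the 50/150 um near/far split)."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class ScreenConfig(_Strict):
    width_cm: float = Field(60.0, gt=0)
    height_cm: float = Field(34.0, gt=0)
    distance_cm: float = Field(20.0, gt=0)


class StimulusConfig(_Strict):
    update_rate_hz: float = Field(4.0, gt=0)
    sf_max_cpd: float = Field(0.15, gt=0)
    duration_s: float = Field(1200.0, gt=0)


class CalciumConfig(_Strict):
    tau_half_ms: float = Field(135.0, gt=0)
    n_spline_knots: int = Field(10, ge=4)


class FitSection(_Strict):
    n_lags: int = Field(8, ge=1)
    penalty_grid: tuple[float, ...] = (1e1, 1e2, 1e3, 1e4, 1e5)
    n_folds: int = Field(5, ge=2)
    max_als_iters: int = Field(30, ge=1)
    tol: float = Field(1e-6, gt=0)
    r_L_threshold: float = Field(0.15, ge=0)

    @field_validator("penalty_grid")
    @classmethod
    def _positive_grid(cls, v):
        if len(v) == 0 or any(p <= 0 for p in v):
            raise ValueError("penalty_grid must be non-empty and positive")
        return tuple(sorted(float(p) for p in v))


class SelectionConfig(_Strict):
    min_cells: int = Field(20, ge=0)


class ClusteringConfig(_Strict):
    bin_width_um: float = Field(30.0, gt=0)
    max_distance_um: float = Field(210.0, gt=0)
    near_um: float = Field(50.0, gt=0)
    far_um: float = Field(150.0, gt=0)
    n_boot: int = Field(200, ge=0)
    kurtosis_threshold: float = Field(15.0, gt=0)
    peak_sf_threshold_cpd: float = Field(0.025, gt=0)
    roi_keep_fraction: float = Field(0.8, gt=0, le=1)

    @property
    def bin_edges_um(self) -> tuple[float, ...]:
        import numpy as np

        return tuple(np.arange(0.0, self.max_distance_um + 1e-9, self.bin_width_um))


class SimulateConfig(_Strict):
    enabled: bool = True
    n_cells: int = Field(50, ge=2)
    field_um: float = Field(250.0, gt=0)
    plane_depths_um: tuple[float, ...] = (0.0,)
    map_length_um: float = Field(38.0, ge=0)
    column_decorrelation: float = Field(0.0, ge=0, le=1)
    interneuron_fraction: float = Field(0.1, ge=0, le=1)
    low_sf_bias_weight: float = Field(0.35, ge=0)


class PipelineConfig(_Strict):
    screen: ScreenConfig = ScreenConfig()
    stimulus: StimulusConfig = StimulusConfig()
    imaging_rate_hz: float = Field(15.5, gt=0)
    calcium: CalciumConfig = CalciumConfig()
    fit: FitSection = FitSection()
    selection: SelectionConfig = SelectionConfig()
    clustering: ClusteringConfig = ClusteringConfig()
    simulate: SimulateConfig = SimulateConfig()
    seed: int = 0

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.model_dump(), sort_keys=True))


def load_config(path) -> PipelineConfig:
    """Load and validate a YAML config; an empty file gives all defaults.

    Unknown keys are rejected with an error naming them.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    data = yaml.safe_load(path.read_text())
    if data is None:
        data = {}
    return PipelineConfig.model_validate(data)
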