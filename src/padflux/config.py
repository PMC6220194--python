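"""Experiment configuration: schema, validation, YAML round-trip.

A single structured text file defines the whole synthetic experiment —
analysis units with colony parameters, noise model, multiplex schedule,
media schedule, sampling and seed — and the analysis defaults (band,
thresholds, counting window, budding index, switch buffer).  Validation is
strict: unknown keys are rejected and violations are reported with field
paths.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

from .detection import DetectionConfig, default_threshold
from .media import MediaSchedule
from .schedule import MultiplexSchedule
from .synthetic import ColonyParams, NoiseModel

__all__ = ["ExperimentConfig", "ConfigError", "load_config", "save_config"]


class ConfigError(ValueError):
    """Configuration file invalid; message lists offending field paths."""


class _StrictModel(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class NoiseConfig(_StrictModel):
    gaussian_sd: float = Field(5e-4, ge=0)
    drift_amplitude: float = Field(5e-3, ge=0)
    drift_period_s: float = Field(300.0, ge=0)
    peak_amplitude_median: float = Field(4e-3, ge=0)
    peak_amplitude_log_sd: float = Field(0.15, ge=0)
    peak_width_mean_s: float = Field(0.020, ge=0)
    peak_width_sd_s: float = Field(0.002, ge=0)

    def to_domain(self) -> NoiseModel:
        return NoiseModel(
            gaussian_sd=self.gaussian_sd,
            drift_amplitude=self.drift_amplitude,
            drift_period=self.drift_period_s,
            peak_amplitude_median=self.peak_amplitude_median,
            peak_amplitude_log_sd=self.peak_amplitude_log_sd,
            peak_width_mean=self.peak_width_mean_s,
            peak_width_sd=self.peak_width_sd_s,
        )


class MediaSegmentConfig(_StrictModel):
    start_s: float = Field(ge=0)
    condition: str


class MediaConfig(_StrictModel):
    segments: list[MediaSegmentConfig] = Field(
        default_factory=lambda: [MediaSegmentConfig(start_s=0.0, condition="YPD")]
    )
    switch_duration_s: float = Field(40.0, ge=0)

    def to_domain(self) -> MediaSchedule:
        return MediaSchedule(
            segments=[(s.start_s, s.condition) for s in self.segments],
            switch_duration=self.switch_duration_s,
        )


class ScheduleConfig(_StrictModel):
    """Round-robin multiplexing; omit to record every unit continuously."""

    window_length_s: float = Field(240.0, gt=0)
    switching_overhead_s: float = Field(0.0, ge=0)


class ColonyConfig(_StrictModel):
    growth_rate_per_cell_per_h: float = Field(0.288, ge=0)
    cells_per_pad: int = Field(400, ge=1)
    initial_cells: Optional[int] = Field(None, ge=0)  # default: pre-filled
    budding_index: float = Field(0.6, ge=0, le=1)
    fill_model: Literal["deterministic-exponential", "stochastic-birth"] = (
        "deterministic-exponential"
    )
    condition_rates_per_h: Optional[dict[str, float]] = None

    def to_domain(self, pads_filled: int) -> ColonyParams:
        capacity = self.cells_per_pad * max(pads_filled, 1)
        return ColonyParams(
            growth_rate_per_cell=self.growth_rate_per_cell_per_h,
            pad_capacity=capacity,
            initial_cells=capacity if self.initial_cells is None else self.initial_cells,
            budding_index=self.budding_index,
            fill_model=self.fill_model,
            condition_rates=self.condition_rates_per_h,
        )


class DetectionOverrides(_StrictModel):
    band_low_hz: Optional[float] = Field(None, gt=0)
    band_high_hz: Optional[float] = Field(None, gt=0)
    threshold_deg: Optional[float] = Field(None, gt=0)
    min_separation_s: Optional[float] = Field(None, ge=0)


class UnitConfig(_StrictModel):
    unit_id: str
    chamber_id: str = "chamber1"
    pads_filled: int = Field(4, ge=0, le=4)
    frequency_hz: float = Field(1.5e6, gt=0)
    colony: ColonyConfig = Field(default_factory=ColonyConfig)
    detection: Optional[DetectionOverrides] = None


class ExperimentConfig(_StrictModel):
    """Top-level experiment description.

    ``t_eis_s`` is the time from experiment start (cell loading) until
    impedance recording begins; it is metadata carried into reports, not an
    offset applied to trace times.
    """

    units: list[UnitConfig]
    duration_s: float = Field(gt=0)
    seed: int
    sampling_rate_hz: float = Field(1000.0, ge=100)
    t_eis_s: float = Field(0.0, ge=0)
    media: MediaConfig = Field(default_factory=MediaConfig)
    schedule: Optional[ScheduleConfig] = Field(default_factory=ScheduleConfig)
    noise: NoiseConfig = Field(default_factory=NoiseConfig)
    band_low_hz: float = Field(0.1, gt=0)
    band_high_hz: float = Field(30.0, gt=0)
    threshold_deg: Optional[float] = Field(None, gt=0)  # default chosen per frequency
    min_separation_s: float = Field(0.05, ge=0)
    count_window_s: float = Field(240.0, gt=0)
    budding_index: float = Field(0.6, ge=0, le=1)
    switch_buffer_s: Optional[float] = Field(None, ge=0)  # default: switch duration

    @model_validator(mode="after")
    def _check(self) -> "ExperimentConfig":
        ids = [u.unit_id for u in self.units]
        if len(ids) != len(set(ids)):
            raise ValueError("unit_id values must be unique")
        if self.band_low_hz >= self.band_high_hz:
            raise ValueError("band_low_hz must be below band_high_hz")
        if self.band_high_hz >= self.sampling_rate_hz / 2:
            raise ValueError("band_high_hz must be below half the sampling rate")
        starts = [s.start_s for s in self.media.segments]
        if starts and (starts[0] != 0.0 or any(b <= a for a, b in zip(starts, starts[1:]))):
            raise ValueError("media.segments must start at 0 with strictly increasing start_s")
        return self

    # -- domain object accessors -------------------------------------------

    def media_schedule(self) -> MediaSchedule:
        return self.media.to_domain()

    def multiplex_schedule(self) -> Optional[MultiplexSchedule]:
        if self.schedule is None:
            return None
        return MultiplexSchedule(
            entries=[(u.unit_id, self.schedule.window_length_s) for u in self.units],
            switching_overhead=self.schedule.switching_overhead_s,
        )

    def detection_config(self, unit: UnitConfig) -> DetectionConfig:
        ov = unit.detection or DetectionOverrides()
        threshold = ov.threshold_deg or self.threshold_deg
        if threshold is None:
            threshold = default_threshold(unit.frequency_hz)
        return DetectionConfig(
            band_low=ov.band_low_hz or self.band_low_hz,
            band_high=ov.band_high_hz or self.band_high_hz,
            threshold=threshold,
            min_separation=(
                self.min_separation_s if ov.min_separation_s is None else ov.min_separation_s
            ),
        )

    @property
    def effective_switch_buffer(self) -> float:
        return (
            self.media.switch_duration_s if self.switch_buffer_s is None else self.switch_buffer_s
        )


def _format_validation_error(err: ValidationError) -> str:
    lines = []
    for e in err.errors():
        path = ".".join(str(p) for p in e["loc"]) or "<root>"
        lines.append(f"  {path}: {e['msg']}")
    return "invalid experiment config:\n" + "\n".join(lines)


def load_config(path: str | Path) -> ExperimentConfig:
    """Load and validate a YAML/JSON experiment config; defaults applied."""
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    try:
        return ExperimentConfig.model_validate(raw)
    except ValidationError as err:
        raise ConfigError(f"{path}: {_format_validation_error(err)}") from err


def save_config(config: ExperimentConfig, path: str | Path) -> Path:
    """Write a config back to YAML; ``load_config`` of the result is equal."""
    path = Path(path)
    with open(path, "w") as fh:
        yaml.safe_dump(config.model_dump(mode="json"), fh, sort_keys=False)
    return path
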