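"""Validated run configuration (JSON) for the command-line workflows.

Unknown keys are rejected; every block converts into the corresponding
domain object.  Field names mirror the on-disk JSON keys, units included.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

from pydantic import BaseModel, ConfigDict, Field, ValidationError

from .pore_physics import (
    MeasurementConfig,
    PoreGeometry,
    SizeCalibration,
)
from .pulse_detection import DetectorSettings
from .trace_sim import AggregationParams, BeadSpec, OffAxisModel

__all__ = ["RunConfig", "ConfigError", "load_config"]


class ConfigError(ValueError):
    """Configuration file failed validation."""


class _Block(BaseModel):
    model_config = ConfigDict(extra="forbid")


class PoreBlock(_Block):
    diameter_nm: float = 1200.0
    thickness_nm: float = 50.0
    resistivity_ohm_m: float = 0.625

    def to_geometry(self) -> PoreGeometry:
        return PoreGeometry(
            diameter_m=self.diameter_nm * 1e-9,
            thickness_m=self.thickness_nm * 1e-9,
            resistivity_ohm_m=self.resistivity_ohm_m,
        )


class MeasurementBlock(_Block):
    voltage_V: float = 0.1
    duration_s: float = 600.0
    sampling_rate_hz: float = 250_000.0
    cis_uL: float = 18.0
    trans_uL: float = 15.0
    height_mm: float = 3.0

    def to_measurement(self) -> MeasurementConfig:
        return MeasurementConfig(
            voltage_v=self.voltage_V,
            duration_s=self.duration_s,
            sampling_rate_hz=self.sampling_rate_hz,
            cis_volume_ul=self.cis_uL,
            trans_volume_ul=self.trans_uL,
            height_difference_m=self.height_mm * 1e-3,
        )


class CalibrationBlock(_Block):
    quad_coeff_nA_per_nm2: float = 1.5 / 300.0**2
    noise_sigma_nA: float = 0.21
    detect_k: float = 5.0

    def to_calibration(self) -> SizeCalibration:
        return SizeCalibration(
            quad_coeff_na_per_nm2=self.quad_coeff_nA_per_nm2,
            noise_sigma_na=self.noise_sigma_nA,
            detect_k=self.detect_k,
        )


class BeadBlock(_Block):
    diameter_nm: float
    concentration_per_ml: float
    label: str = ""

    def to_bead(self) -> BeadSpec:
        return BeadSpec(
            diameter_nm=self.diameter_nm,
            concentration_per_ml=self.concentration_per_ml,
            label=self.label,
        )


class AggregationBlock(_Block):
    half_sat_K_molar: float = 2.94e-13
    max_mean_cluster_beta: float = 9.9
    self_agg_fraction: float = 0.05
    amplitude_table_nA: list[float] = Field(default=[1.5, 2.8, 3.5, 6.0])
    extrapolation_exponent: float = 2.0 / 3.0

    def to_params(self) -> AggregationParams:
        return AggregationParams(
            half_sat_k_molar=self.half_sat_K_molar,
            max_mean_cluster_beta=self.max_mean_cluster_beta,
            self_agg_fraction=self.self_agg_fraction,
            amplitude_table_na=tuple(self.amplitude_table_nA),
            extrapolation_exponent=self.extrapolation_exponent,
        )


class OffAxisBlock(_Block):
    probability: float = 0.2
    factor: float = 1.35
    cv_at_reference: float = 0.04
    reference_diameter_nm: float = 300.0

    def to_model(self) -> OffAxisModel:
        return OffAxisModel(
            probability=self.probability,
            factor=self.factor,
            cv_at_reference=self.cv_at_reference,
            reference_diameter_nm=self.reference_diameter_nm,
        )


class SimulationBlock(_Block):
    mixture: list[BeadBlock] = Field(default_factory=list)
    antigen_conc_molar: float | None = None
    aggregation: AggregationBlock = Field(default_factory=AggregationBlock)
    off_axis: OffAxisBlock = Field(default_factory=OffAxisBlock)
    rate_coeff: float = 2.15e-7
    seed: int = 0


class DetectionBlock(_Block):
    baseline_window_s: float = 0.05
    k_sigma: float = 5.0
    min_separation_ms: float = 0.2
    width_definition: str = "fwhm"
    smooth_window_ms: float = 0.2
    min_width_samples: int = 3

    def to_settings(self) -> DetectorSettings:
        return DetectorSettings(
            baseline_window_s=self.baseline_window_s,
            k_sigma=self.k_sigma,
            min_separation_ms=self.min_separation_ms,
            width_definition=self.width_definition,
            smooth_window_ms=self.smooth_window_ms,
            min_width_samples=self.min_width_samples,
        )


class AnalysisBlock(_Block):
    cut_points_nA: list[float] = Field(default=[3.0, 5.9])
    class_labels: list[str] = Field(default_factory=list)
    coincidence_ip_cut_nA: float = 10.0
    coincidence_td_cut_ms: float = 7.0
    mono_amplitude_nA: float = 1.5


class RunConfig(_Block):
    """Top-level configuration: every workflow echoes its resolved copy."""

    pore: PoreBlock = Field(default_factory=PoreBlock)
    measurement: MeasurementBlock = Field(default_factory=MeasurementBlock)
    calibration: CalibrationBlock = Field(default_factory=CalibrationBlock)
    simulation: SimulationBlock = Field(default_factory=SimulationBlock)
    detection: DetectionBlock = Field(default_factory=DetectionBlock)
    analysis: AnalysisBlock = Field(default_factory=AnalysisBlock)

    def digest(self) -> str:
        """Stable hash of the resolved configuration."""
        payload = json.dumps(self.model_dump(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def load_config(path) -> RunConfig:
    """Parse and validate a JSON config file; unknown keys are rejected."""
    try:
        raw = json.loads(Path(path).read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise ConfigError(f"{path}: {exc}") from exc
    try:
        return RunConfig.model_validate(raw)
    except ValidationError as exc:
        raise ConfigError(f"{path}: {exc}") from exc
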