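"""End-to-end wiring: raw EMG -> activation -> calibration -> angle.

The full causal chain is

    highpass -> rectify -> activation dynamics -> lowpass -> MVC
    normalization -> activation nonlinearity -> (dead band) -> state machine

Calibration runs exactly the same causal chain on the calibration trial and
fits the quadratic map between its activation output and the recorded
angles; prediction trials therefore see the same filter latency that the
map was fitted with, which keeps the two self-consistent.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional, Union

import numpy as np
import yaml

from . import emg_processing as emg
from .calibration import CalibrationModel, detect_flexion_phase, fit_quadratic_map
from .emg_processing import EMGTrace
from .exceptions import ParameterError
from .state_machine import TrendDetector, run

__all__ = ["PipelineConfig", "process_to_activation", "calibrate", "predict_angles"]


@dataclass(frozen=True)
class PipelineConfig:
    """Flat configuration of every tunable pipeline parameter.

    Defaults: 4th-order 10 Hz high-pass; recursive dynamics poles
    gamma1 = gamma2 = -0.5 with a 50-sample electromechanical delay;
    2nd-order 1.0 Hz low-pass; nonlinearity shape A = 0.5 with R = 1/A so a
    normalized excitation in [0, 1] maps onto activation in [0, 1];
    2 % dead band; holding threshold at 90 % of the peak flexion activation.
    """

    highpass_cutoff: float = 10.0
    highpass_order: int = 4
    gamma1: float = -0.5
    gamma2: float = -0.5
    delay_samples: int = 50
    lowpass_cutoff: float = 1.0
    lowpass_order: int = 2
    R: float = 2.0
    A: float = 0.5
    dead_band: float = 0.02
    kappa: float = 0.9
    dtheta_threshold: float = 5.0
    trend_window_s: float = 0.25
    trend_debounce_s: float = 0.1
    p_max: float = 3.0

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ParameterError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def save(self, path: Union[str, Path]) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def load(cls, path: Union[str, Path]) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, dict):
            raise ParameterError(f"config file {path} does not hold a mapping")
        return cls.from_dict(data)

    def filter_coefficients(self) -> emg.FilterCoefficients:
        return emg.make_filter_coefficients(
            self.gamma1, self.gamma2, self.delay_samples
        )

    def activation_params(self, mvc_value: float) -> emg.ActivationParams:
        return emg.ActivationParams(
            R=self.R, A=self.A, mvc_value=mvc_value, dead_band=self.dead_band
        )

    def trend_detector(self) -> TrendDetector:
        return TrendDetector(
            window_s=self.trend_window_s,
            hysteresis=self.dead_band,
            debounce_s=self.trend_debounce_s,
        )


def process_to_activation(
    raw: EMGTrace, mvc_value: float, config: Optional[PipelineConfig] = None
) -> EMGTrace:
    """Run the full conditioning chain on a raw trace (no dead band)."""
    if config is None:
        config = PipelineConfig()
    params = config.activation_params(mvc_value)
    u = emg.activation_dynamics(
        emg.rectify(
            emg.highpass_filter(raw, config.highpass_cutoff, config.highpass_order)
        ),
        config.filter_coefficients(),
    )
    u = emg.lowpass_smooth(u, config.lowpass_cutoff, config.lowpass_order)
    u = emg.normalize_mvc(u, mvc_value)
    return emg.activation_nonlinearity(u, params)


def calibrate(
    raw: EMGTrace,
    angles_deg: np.ndarray,
    mvc_value: float,
    config: Optional[PipelineConfig] = None,
) -> CalibrationModel:
    """Fit the quadratic map and thresholds from one recorded trial."""
    if config is None:
        config = PipelineConfig()
    angles = np.asarray(angles_deg, dtype=float)
    if angles.size != len(raw):
        raise ParameterError("angle series must match the EMG trace length")
    activation = process_to_activation(raw, mvc_value, config)
    mask = detect_flexion_phase(
        angles, raw.sampling_rate, config.dtheta_threshold
    )
    return fit_quadratic_map(
        activation,
        angles,
        mask,
        R=config.R,
        kappa=config.kappa,
        dead_band=config.dead_band,
    )


def predict_angles(
    raw: EMGTrace,
    model: CalibrationModel,
    mvc_value: float,
    config: Optional[PipelineConfig] = None,
    return_states: bool = False,
):
    """Predict the elbow-angle series (degrees) from a raw EMG trace."""
    if config is None:
        config = PipelineConfig()
    activation = process_to_activation(raw, mvc_value, config)
    return run(
        activation,
        model,
        detector=config.trend_detector(),
        dead_band=config.dead_band,
        p_max=config.p_max,
        return_states=return_states,
    )
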