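"""Per-subject calibration of the activation-to-angle quadratic map.

During elbow flexion the scaled activation a/R and cos^2(theta) obey a
quadratic relationship (a consequence of the log-transformed Hill-type
model with lumped constants).  Calibration fits that polynomial by least
squares on the flexion-phase samples of one trial where the true angle was
recorded, and derives the two state-machine thresholds from the same trial:

* ``holding_threshold``: a fraction kappa (default 0.9) of the peak
  flexion-phase activation — the level above which the holding state is
  reachable;
* ``inactivation_level``: max(dead_band, 5 % of the peak activation) — the
  level below which the arm is considered relaxed.

The fitted model also records ``release_band``, the relative rectification
range a_r; the holding state releases into extension once activation falls
below ``holding_threshold * (1 - release_band)``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Union

import numpy as np

from .emg_processing import EMGTrace
from .exceptions import CalibrationError, ParameterError

__all__ = [
    "CalibrationModel",
    "fit_quadratic_map",
    "invert_map",
    "detect_flexion_phase",
]

_MIN_FLEXION_SAMPLES = 10


@dataclass(frozen=True)
class CalibrationModel:
    """Fitted quadratic map from activation to cos^2(theta) plus thresholds.

    ``poly_coeffs`` are ascending coefficients (c0, c1, c2) of the polynomial
    in x = a/R.  Predicted cos^2(theta) is clamped to [0, 1] before the
    inversion ``theta = arccos(sqrt(.))``, which makes the inverse total and
    confined to [0, 90] degrees.
    """

    poly_coeffs: tuple
    R: float
    holding_threshold: float
    inactivation_level: float
    fit_r: float
    release_band: float = 0.02
    monotone_warning: bool = False

    def __post_init__(self) -> None:
        if len(self.poly_coeffs) != 3:
            raise ParameterError("poly_coeffs must have three entries")
        object.__setattr__(self, "poly_coeffs", tuple(float(c) for c in self.poly_coeffs))
        if not self.R > 0:
            raise ParameterError("R must be positive")
        if not 0.0 < self.inactivation_level < self.holding_threshold < 1.0:
            raise ParameterError(
                "thresholds must satisfy 0 < inactivation_level < "
                "holding_threshold < 1"
            )

    def predict_cos2(self, a):
        """Predicted cos^2(theta) for activation a, clamped to [0, 1]."""
        x = np.asarray(a, dtype=float) / self.R
        c0, c1, c2 = self.poly_coeffs
        return np.clip(c0 + c1 * x + c2 * x * x, 0.0, 1.0)

    def invert(self, a):
        """Elbow angle in degrees for activation a; always in [0, 90]."""
        theta = np.degrees(np.arccos(np.sqrt(self.predict_cos2(a))))
        if np.isscalar(a):
            return float(theta)
        return theta

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "poly_coeffs": list(self.poly_coeffs),
            "R": self.R,
            "holding_threshold": self.holding_threshold,
            "inactivation_level": self.inactivation_level,
            "fit_r": self.fit_r,
            "release_band": self.release_band,
            "monotone_warning": self.monotone_warning,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationModel":
        return cls(
            poly_coeffs=tuple(d["poly_coeffs"]),
            R=float(d["R"]),
            holding_threshold=float(d["holding_threshold"]),
            inactivation_level=float(d["inactivation_level"]),
            fit_r=float(d["fit_r"]),
            release_band=float(d.get("release_band", 0.02)),
            monotone_warning=bool(d.get("monotone_warning", False)),
        )

    def save(self, path: Union[str, Path]) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def load(cls, path: Union[str, Path]) -> "CalibrationModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _as_array(activation) -> np.ndarray:
    if isinstance(activation, EMGTrace):
        return activation.samples
    return np.asarray(activation, dtype=float)


def fit_quadratic_map(
    activation,
    angles_deg,
    flexion_mask,
    *,
    R: float = 2.0,
    kappa: float = 0.9,
    dead_band: float = 0.02,
) -> CalibrationModel:
    """Least-squares quadratic fit of flexion-phase activation to cos^2(theta).

    Parameters
    ----------
    activation
        Activation trace (:class:`EMGTrace` at the activation stage or a
        plain array in [0, 1]).
    angles_deg
        Simultaneously recorded elbow angles in degrees, [0, 90].
    flexion_mask
        Boolean series marking flexion-phase samples (see
        :func:`detect_flexion_phase`).
    R
        Excitation scaling used when forming the regressor x = a/R.
    kappa
        Holding-threshold fraction of the peak flexion activation.
    dead_band
        Relative rectification range; floors the inactivation level and is
        stored as the model's release band.

    Returns
    -------
    CalibrationModel
        Including ``fit_r``, the Pearson correlation between fitted and
        observed cos^2(theta) on the flexion phase.
    """
    a = _as_array(activation)
    theta = np.asarray(angles_deg, dtype=float)
    mask = np.asarray(flexion_mask, dtype=bool)
    if not (a.shape == theta.shape == mask.shape):
        raise ParameterError("activation, angles and mask must share a shape")
    if np.any(theta < 0) or np.any(theta > 90):
        raise ParameterError("angles must lie in [0, 90] degrees")
    n = int(mask.sum())
    if n < _MIN_FLEXION_SAMPLES:
        raise CalibrationError(
            f"flexion phase has {n} samples; at least {_MIN_FLEXION_SAMPLES} required"
        )
    x = a[mask] / R
    theta_rad = np.radians(theta[mask])
    y = np.cos(theta_rad) ** 2
    if np.ptp(x) == 0:
        raise CalibrationError("activation is constant over the flexion phase")
    # weight residuals by the local angle sensitivity |d theta / d cos^2|
    # ~ 1/sin(2 theta): the model is used through arccos(sqrt(.)), so an
    # unweighted cos^2 fit would tolerate large *angle* errors near 0 and 90
    # degrees where cos^2 is flat.  Capped to keep the endpoints finite.
    w = 1.0 / np.clip(np.sin(2.0 * theta_rad), 0.1, None)
    c2, c1, c0 = np.polyfit(x, y, 2, w=w)
    fitted = c0 + c1 * x + c2 * x * x
    fit_r = float(np.corrcoef(fitted, y)[0, 1])

    # monotonicity of the fitted map over the observed activation range
    slope = c1 + 2.0 * c2 * np.array([x.min(), x.max()])
    monotone_warning = bool(np.any(slope > 0))
    if monotone_warning:
        warnings.warn(
            "fitted activation-to-cos^2 map is not monotone decreasing over "
            "the calibrated range",
            stacklevel=2,
        )

    peak = float(a[mask].max())
    holding_threshold = kappa * peak
    inactivation_level = max(dead_band, 0.05 * peak)
    return CalibrationModel(
        poly_coeffs=(c0, c1, c2),
        R=R,
        holding_threshold=holding_threshold,
        inactivation_level=inactivation_level,
        fit_r=fit_r,
        release_band=dead_band,
        monotone_warning=monotone_warning,
    )


def invert_map(a, model: CalibrationModel):
    """Angle in degrees for an activation value under a fitted model."""
    return model.invert(a)


def detect_flexion_phase(
    angles_deg,
    sampling_rate: float,
    dtheta_threshold: float = 5.0,
    min_duration_s: float = 0.2,
    smooth_s: float = 0.1,
) -> np.ndarray:
    """Mark samples whose smoothed angular velocity exceeds +dtheta_threshold.

    Contiguous runs shorter than ``min_duration_s`` are discarded; raises
    :class:`CalibrationError` when no flexion segment remains.
    """
    theta = np.asarray(angles_deg, dtype=float)
    if theta.size < 2:
        raise CalibrationError("angle series too short for phase detection")
    win = max(1, int(round(smooth_s * sampling_rate)))
    kernel = np.ones(win) / win
    smoothed = np.convolve(theta, kernel, mode="same")
    velocity = np.gradient(smoothed) * sampling_rate
    mask = velocity > dtheta_threshold

    # drop runs shorter than the minimum duration
    min_len = max(1, int(round(min_duration_s * sampling_rate)))
    edges = np.flatnonzero(np.diff(np.concatenate([[0], mask.view(np.int8), [0]])))
    for start, stop in zip(edges[::2], edges[1::2]):
        if stop - start < min_len:
            mask[start:stop] = False
    if not mask.any():
        raise CalibrationError("no flexion segment found in the angle series")
    return mask
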