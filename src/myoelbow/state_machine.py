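"""Four-state switching model turning activation into a continuous elbow angle.

The automaton has the states relaxation, flexion, holding and extension,
mirroring the phases of a voluntary flexion-hold-extension movement:

* relaxation outputs 0 deg and leaves for flexion when activation rises
  above the inactivation level;
* flexion outputs the inverse quadratic map of the activation and remembers
  its last output as theta_max;
* holding freezes the output at theta_max (the activation drops when the
  motion becomes isometric — the flexion "overshoot" — so the raw map would
  wrongly lower the angle); it is entered when activation stops rising above
  the holding threshold F_t and released into extension once activation
  falls below ``F_t*(1 - a_r)``, a_r being the dead-band range.  That
  threshold-crossing release is what produces the characteristic
  peak time lag ``t_lag = (F_p - F_t*(1 - a_r))/gamma`` when a flexion is
  followed immediately by an extension;
* extension outputs ``p * invert(a)`` with the proportional gain
  ``p = theta_max / theta'_max`` fixed at entry so the output is continuous
  across the holding-to-extension switch, and returns to relaxation at the
  inactivation level (or back to flexion on a rising trend).

``run`` is expressible as repeated ``step`` calls carrying only the
:class:`SwitchState` and the trend-detector window, so the model is
streaming-capable at the EMG sampling rate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Optional, Tuple

import numpy as np

from .calibration import CalibrationModel
from .emg_processing import EMGTrace, dead_band_rectify
from .exceptions import ParameterError

__all__ = [
    "RELAXATION",
    "FLEXION",
    "HOLDING",
    "EXTENSION",
    "RISING",
    "FLAT",
    "FALLING",
    "SwitchState",
    "TrendDetector",
    "step",
    "run",
    "proportional_gain",
    "predicted_time_lag",
]

RELAXATION = "relaxation"
FLEXION = "flexion"
HOLDING = "holding"
EXTENSION = "extension"
_STATE_NAMES = (RELAXATION, FLEXION, HOLDING, EXTENSION)

RISING = "rising"
FLAT = "flat"
FALLING = "falling"
_TRENDS = (RISING, FLAT, FALLING)

#: default saturation for the proportional gain when theta'_max is tiny
DEFAULT_P_MAX = 3.0

#: a trend requires the signal to move this many dead-band widths per window
_TREND_BANDS_PER_WINDOW = 2.0


@dataclass(frozen=True)
class SwitchState:
    """Automaton state plus the per-trial memory it carries.

    ``theta_max`` is the last flexion-state output, ``theta_prime_max`` the
    inverse-map angle at the first extension sample, ``p`` the continuity
    gain and ``held_angle`` the frozen output while holding.
    """

    name: str = RELAXATION
    theta_max: float = 0.0
    theta_prime_max: float = float("nan")
    p: float = 1.0
    held_angle: float = 0.0

    def __post_init__(self) -> None:
        if self.name not in _STATE_NAMES:
            raise ParameterError(f"unknown state {self.name!r}")


@dataclass(frozen=True)
class TrendDetector:
    """Classify the activation trend as rising, flat or falling.

    The slope of a least-squares line over a trailing ``window_s`` window is
    compared with a hysteresis band: the signal must move
    ``2 * hysteresis * max(a, hysteresis)`` within one window to count as a
    trend, otherwise it is flat.  A raw classification must persist for
    ``debounce_s`` before the reported trend switches, which keeps envelope
    wobble from flickering the automaton.  ``hysteresis`` reuses the
    dead-band range of the value rectification filter.
    """

    window_s: float = 0.25
    hysteresis: float = 0.02
    debounce_s: float = 0.1

    def __post_init__(self) -> None:
        if not self.window_s > 0 or not self.hysteresis > 0:
            raise ParameterError("window_s and hysteresis must be positive")
        if self.debounce_s < 0:
            raise ParameterError("debounce_s must be non-negative")

    def window_samples(self, sampling_rate: float) -> int:
        n = int(round(self.window_s * sampling_rate))
        if n < 2:
            raise ParameterError("trend window must span at least 2 samples")
        return n

    def slopes(self, a: np.ndarray, sampling_rate: float) -> np.ndarray:
        """Trailing least-squares slope (units per second) at every sample."""
        n = self.window_samples(sampling_rate)
        idx = np.arange(n, dtype=float)
        w = (idx - idx.mean()) / np.sum((idx - idx.mean()) ** 2) * sampling_rate
        # trailing window: slope[t] = sum_j w[j] * a[t-n+1+j]
        full = np.convolve(a, w[::-1])
        slopes = np.zeros_like(a)
        slopes[n - 1 :] = full[n - 1 : a.size]
        return slopes

    def classify(self, a: np.ndarray, sampling_rate: float) -> np.ndarray:
        """Debounced trend labels (one of the module trend constants)."""
        a = np.asarray(a, dtype=float)
        slopes = self.slopes(a, sampling_rate)
        thresh = (
            _TREND_BANDS_PER_WINDOW
            * self.hysteresis
            * np.maximum(a, self.hysteresis)
            / self.window_s
        )
        raw = np.where(slopes > thresh, 1, np.where(slopes < -thresh, -1, 0))
        need = max(1, int(round(self.debounce_s * sampling_rate)))
        out = np.empty(a.size, dtype=np.int8)
        current = 0
        candidate = 0
        count = 0
        for i in range(a.size):
            r = raw[i]
            if r == current:
                candidate, count = r, 0
            elif r == candidate:
                count += 1
                if count >= need:
                    current, count = r, 0
            else:
                candidate, count = r, 1
                if need <= 1:
                    current, count = r, 0
            out[i] = current
        labels = np.array([FALLING, FLAT, RISING])
        return labels[out + 1]


def proportional_gain(
    theta_max: float, theta_prime_max: float, p_max: float = DEFAULT_P_MAX
) -> float:
    """Continuity gain ``p = theta_max / theta'_max``, saturated at p_max."""
    if theta_prime_max <= 0:
        warnings.warn(
            "theta'_max is not positive; proportional gain saturated at p_max",
            stacklevel=2,
        )
        return p_max
    return min(theta_max / theta_prime_max, p_max)


def step(
    state: SwitchState,
    a_t: float,
    trend: str,
    model: CalibrationModel,
    p_max: float = DEFAULT_P_MAX,
) -> Tuple[SwitchState, float]:
    """Advance the automaton by one sample and emit the angle output.

    Transitions are evaluated first, then the output is produced by the state
    in effect for this sample, which makes the holding-to-extension output
    continuous by construction of the proportional gain.
    """
    if trend not in _TRENDS:
        raise ParameterError(f"unknown trend {trend!r}")
    name = state.name
    entering_extension = False

    if name == RELAXATION:
        if trend == RISING and a_t > model.inactivation_level:
            name = FLEXION
    elif name == FLEXION:
        if trend != RISING and a_t > model.holding_threshold:
            name = HOLDING
    elif name == HOLDING:
        if a_t < model.holding_threshold * (1.0 - model.release_band):
            name = EXTENSION
            entering_extension = True
    elif name == EXTENSION:
        if a_t <= model.inactivation_level:
            name = RELAXATION
        elif trend == RISING:
            name = FLEXION

    if name == RELAXATION:
        new_state = SwitchState(RELAXATION)
        return new_state, 0.0
    if name == FLEXION:
        theta = model.invert(a_t)
        return replace(state, name=FLEXION, theta_max=theta), theta
    if name == HOLDING:
        theta = state.theta_max
        return replace(state, name=HOLDING, held_angle=theta), theta
    # extension
    if entering_extension:
        theta_prime_max = model.invert(a_t)
        p = proportional_gain(state.theta_max, theta_prime_max, p_max)
        state = replace(
            state, name=EXTENSION, theta_prime_max=theta_prime_max, p=p
        )
    theta = float(np.clip(state.p * model.invert(a_t), 0.0, 90.0))
    return replace(state, name=EXTENSION), theta


def run(
    a,
    model: CalibrationModel,
    detector: Optional[TrendDetector] = None,
    sampling_rate: Optional[float] = None,
    dead_band: Optional[float] = None,
    p_max: float = DEFAULT_P_MAX,
    return_states: bool = False,
):
    """Run the switching model over a whole activation trace.

    Applies the dead-band rectification, classifies the trend per sample and
    iterates :func:`step`.  ``a`` may be an activation :class:`EMGTrace`
    (sampling rate taken from the trace) or a plain array with
    ``sampling_rate`` given.  Returns the angle series in degrees, plus the
    per-sample state names when ``return_states`` is true.
    """
    if isinstance(a, EMGTrace):
        x = a.samples
        fs = a.sampling_rate
    else:
        x = np.asarray(a, dtype=float)
        if sampling_rate is None:
            raise ParameterError("sampling_rate is required for array input")
        fs = sampling_rate
    if dead_band is None:
        dead_band = model.release_band
    if detector is None:
        detector = TrendDetector(hysteresis=max(dead_band, 0.01))

    rectified = dead_band_rectify(x, dead_band)
    trends = detector.classify(rectified, fs)

    state = SwitchState()
    angles = np.empty(x.size)
    states = np.empty(x.size, dtype=object) if return_states else None
    for i in range(x.size):
        state, angles[i] = step(state, rectified[i], trends[i], model, p_max)
        if states is not None:
            states[i] = state.name
    if return_states:
        return angles, states
    return angles


def predicted_time_lag(
    peak_activation: float,
    holding_threshold: float,
    dead_band: float,
    decrease_rate: float,
) -> float:
    """Peak time lag ``t_lag = (F_p - F_t*(1 - a_r)) / gamma`` in seconds.

    Diagnostic only: the time the model spends leaving the holding state when
    a flexion is immediately followed by an extension, given the activation
    decrease rate gamma (units of activation per second).
    """
    if not decrease_rate > 0:
        raise ParameterError("decrease_rate must be positive")
    return (peak_activation - holding_threshold * (1.0 - dead_band)) / decrease_rate
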