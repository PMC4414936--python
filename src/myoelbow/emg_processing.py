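"""Surface-EMG conditioning and muscle-activation estimation.

The processing chain turns a raw single-channel surface-EMG recording into a
bounded, smooth muscle activation signal a(t) in [0, 1]:

1. causal fourth-order Butterworth high-pass (10 Hz) to remove DC offset and
   motion artefact,
2. full-wave rectification,
3. second-order recursive activation dynamics with an electromechanical
   delay d, ``u(t) = alpha*e(t-d) - beta1*u(t-1) - beta2*u(t-2)``, whose
   coefficients are parameterized by two poles gamma1, gamma2 with
   ``alpha - beta1 - beta2 = 1`` so the DC gain is exactly one,
4. causal second-order Butterworth low-pass (0.5-1 Hz) giving the slow
   activation envelope that muscle force can actually follow,
5. normalization by the peak envelope recorded during a maximum voluntary
   contraction (MVC) test,
6. an exponential shape function ``a(u) = (exp(u/R) - 1)/(exp(A) - 1)``
   mapping neural excitation to mechanical activation,
7. an optional dead-band rectification (1-3 % staircase) that suppresses the
   slow drift of the EMG envelope at rest.

All filters are causal: the chain is a real-time control reference, so
zero-phase (forward-backward) filtering is never used, including during
calibration.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import signal

from .exceptions import DegenerateMVCError, ParameterError, StabilityError

__all__ = [
    "STAGES",
    "EMGTrace",
    "FilterCoefficients",
    "ActivationParams",
    "highpass_filter",
    "rectify",
    "make_filter_coefficients",
    "activation_dynamics",
    "lowpass_smooth",
    "activation_nonlinearity",
    "compute_mvc",
    "normalize_mvc",
    "dead_band_rectify",
]

STAGES = ("raw", "highpassed", "rectified", "excitation", "activation")

#: dead-band range the method treats as physiologically sensible (1-3 %)
DEAD_BAND_RANGE = (0.01, 0.03)


@dataclass(frozen=True)
class EMGTrace:
    """A uniformly sampled single-channel signal plus its processing stage.

    Parameters
    ----------
    samples
        Amplitude values (arbitrary voltage units until MVC normalization).
    sampling_rate
        Sampling frequency in Hz.
    stage
        One of :data:`STAGES`; encodes which processing steps have been
        applied and is checked by each operation's precondition.
    """

    samples: np.ndarray
    sampling_rate: float
    stage: str = "raw"

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        if samples.ndim != 1 or samples.size < 1:
            raise ParameterError("samples must be a non-empty 1-D array")
        if not np.all(np.isfinite(samples)):
            raise ParameterError("samples must be finite")
        if not self.sampling_rate > 0:
            raise ParameterError("sampling_rate must be positive")
        if self.stage not in STAGES:
            raise ParameterError(f"unknown stage {self.stage!r}")
        if self.stage == "rectified" and np.any(samples < 0):
            raise ParameterError("rectified trace must be non-negative")
        if self.stage == "activation" and (
            np.any(samples < 0) or np.any(samples > 1)
        ):
            raise ParameterError("activation trace must lie in [0, 1]")
        object.__setattr__(self, "samples", samples)

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Trace duration in seconds."""
        return self.samples.size / self.sampling_rate

    def time(self) -> np.ndarray:
        """Sample times in seconds, starting at zero."""
        return np.arange(self.samples.size) / self.sampling_rate

    def with_samples(self, samples: np.ndarray, stage: str) -> "EMGTrace":
        """Return a new trace with the same sampling rate."""
        return EMGTrace(samples, self.sampling_rate, stage)


@dataclass(frozen=True)
class FilterCoefficients:
    """Coefficients of the second-order recursive activation dynamics.

    The difference equation is
    ``u(t) = alpha*e(t-d) - beta1*u(t-1) - beta2*u(t-2)`` with
    ``beta1 = gamma1 + gamma2``, ``beta2 = gamma1*gamma2`` and
    ``alpha = 1 + beta1 + beta2`` (unity DC gain).  Stability requires
    ``|gamma1| < 1`` and ``|gamma2| < 1``.
    """

    gamma1: float
    gamma2: float
    alpha: float
    beta1: float
    beta2: float
    delay_samples: int

    def __post_init__(self) -> None:
        if abs(self.gamma1) >= 1 or abs(self.gamma2) >= 1:
            raise StabilityError(
                "recursive poles must satisfy |gamma1| < 1 and |gamma2| < 1"
            )
        if not np.isclose(self.beta1, self.gamma1 + self.gamma2):
            raise ParameterError("beta1 must equal gamma1 + gamma2")
        if not np.isclose(self.beta2, self.gamma1 * self.gamma2):
            raise ParameterError("beta2 must equal gamma1 * gamma2")
        if not np.isclose(self.alpha - self.beta1 - self.beta2, 1.0):
            raise ParameterError("alpha - beta1 - beta2 must equal 1")
        if self.delay_samples < 0 or int(self.delay_samples) != self.delay_samples:
            raise ParameterError("delay_samples must be a non-negative integer")
        object.__setattr__(self, "delay_samples", int(self.delay_samples))


def make_filter_coefficients(
    gamma1: float = -0.5, gamma2: float = -0.5, delay_samples: int = 50
) -> FilterCoefficients:
    """Build stable activation-dynamics coefficients from the two poles.

    Defaults give a critically-damped-like response (both poles at 0.5 in the
    z-plane) with a 50-sample electromechanical delay (50 ms at 1 kHz).
    """
    beta1 = gamma1 + gamma2
    beta2 = gamma1 * gamma2
    alpha = 1.0 + beta1 + beta2
    return FilterCoefficients(gamma1, gamma2, alpha, beta1, beta2, delay_samples)


@dataclass(frozen=True)
class ActivationParams:
    """Shape parameters of the excitation-to-activation nonlinearity.

    ``R`` scales the excitation, ``A`` sets the curvature of
    ``a(u) = (exp(u/R) - 1)/(exp(A) - 1)``; with ``R = 1/A`` a normalized
    excitation u in [0, 1] maps exactly onto a in [0, 1].  The default shape
    is mildly convex (A = 0.5): the calibrated quadratic relation holds in
    the excitation variable, so the excitation-to-activation map must stay
    close to linear for the quadratic to represent the composed relation.
    ``mvc_value`` is the peak rectified-and-smoothed EMG during the MVC test
    and ``dead_band`` the relative rectification range (1-3 %).
    """

    R: float = 2.0
    A: float = 0.5
    mvc_value: float = 1.0
    dead_band: float = 0.02

    def __post_init__(self) -> None:
        if not self.R > 0:
            raise ParameterError("R must be positive")
        if not self.A > 0:
            raise ParameterError("A must be positive (A = 0 is degenerate)")
        if not self.mvc_value > 0:
            raise ParameterError("mvc_value must be positive")
        lo, hi = DEAD_BAND_RANGE
        if not lo <= self.dead_band <= hi:
            raise ParameterError(f"dead_band must lie in [{lo}, {hi}]")


def _butter_sos(
    cutoff_hz: float, sampling_rate: float, order: int, btype: str
) -> np.ndarray:
    if not order >= 1:
        raise ParameterError("filter order must be >= 1")
    nyquist = sampling_rate / 2.0
    if not 0 < cutoff_hz < nyquist:
        raise ParameterError(
            f"cutoff {cutoff_hz} Hz must lie strictly between 0 and the "
            f"Nyquist frequency {nyquist} Hz"
        )
    return signal.butter(order, cutoff_hz, btype=btype, fs=sampling_rate, output="sos")


def highpass_filter(
    trace: EMGTrace, cutoff_hz: float = 10.0, order: int = 4
) -> EMGTrace:
    """Causal Butterworth high-pass removing DC offset and drift.

    Defaults follow the standard surface-EMG conditioning choice of a
    fourth-order filter with a 10 Hz cut-off.
    """
    if trace.stage != "raw":
        raise ParameterError("highpass_filter expects a raw trace")
    sos = _butter_sos(cutoff_hz, trace.sampling_rate, order, "highpass")
    out = signal.sosfilt(sos, trace.samples)
    return trace.with_samples(out, "highpassed")


def rectify(trace: EMGTrace) -> EMGTrace:
    """Full-wave rectification of the high-passed signal."""
    if trace.stage != "highpassed":
        raise ParameterError("rectify expects a highpassed trace")
    return trace.with_samples(np.abs(trace.samples), "rectified")


def activation_dynamics(e: EMGTrace, coeffs: FilterCoefficients) -> EMGTrace:
    """Apply the delayed second-order recursive filter to rectified EMG.

    Implements ``u(t) = alpha*e(t-d) - beta1*u(t-1) - beta2*u(t-2)`` with
    zero initial conditions and ``e(t) = 0`` for t < 0.  The coefficient
    constraint ``alpha - beta1 - beta2 = 1`` makes the DC gain exactly one,
    so a bounded input in [0, 1] produces a bounded output whose steady
    state equals the steady-state input.
    """
    if e.stage != "rectified":
        raise ParameterError("activation_dynamics expects a rectified trace")
    x = e.samples
    d = coeffs.delay_samples
    delayed = np.concatenate([np.zeros(min(d, x.size)), x])[: x.size]
    u = signal.lfilter([coeffs.alpha], [1.0, coeffs.beta1, coeffs.beta2], delayed)
    return e.with_samples(u, "excitation")


def lowpass_smooth(
    u: EMGTrace, cutoff_hz: float = 1.0, order: int = 2
) -> EMGTrace:
    """Causal low-pass giving the slow activation envelope.

    The cut-off sits far below typical force-variation bandwidth (default
    1.0 Hz, order 2, configurable in the 0.5-1 Hz band): muscle acts as a mechanical low-pass, and a very smooth
    envelope is preferred over preserving signal energy because the output is
    a kinematic control reference, not a clinical feature.
    """
    if u.stage not in ("rectified", "excitation"):
        raise ParameterError("lowpass_smooth expects a rectified or excitation trace")
    sos = _butter_sos(cutoff_hz, u.sampling_rate, order, "lowpass")
    out = signal.sosfilt(sos, u.samples)
    return u.with_samples(out, u.stage if u.stage == "excitation" else "excitation")


def activation_nonlinearity(u: EMGTrace, params: ActivationParams) -> EMGTrace:
    """Map normalized excitation to activation via the exponential shape.

    ``a(u) = (exp(u/R) - 1)/(exp(A) - 1)``, clamped to [0, 1].  The map is
    strictly monotone on [0, R*A] and satisfies a(0) = 0, a(R*A) = 1.
    """
    if u.stage != "excitation":
        raise ParameterError("activation_nonlinearity expects an excitation trace")
    a = np.expm1(u.samples / params.R) / np.expm1(params.A)
    return u.with_samples(np.clip(a, 0.0, 1.0), "activation")


def compute_mvc(
    trials: Sequence[EMGTrace],
    highpass_cutoff: float = 10.0,
    highpass_order: int = 4,
    smooth_cutoff: float = 1.0,
    smooth_order: int = 2,
) -> float:
    """Peak smoothed-envelope value over a set of MVC trials.

    Each raw trial is high-passed, rectified and low-pass smoothed with the
    same causal filters as the main chain; the MVC value is the maximum of
    the resulting envelopes over all trials.
    """
    if len(trials) < 1:
        raise ParameterError("compute_mvc needs at least one trial")
    peak = 0.0
    for trial in trials:
        env = lowpass_smooth(
            rectify(highpass_filter(trial, highpass_cutoff, highpass_order)),
            smooth_cutoff,
            smooth_order,
        )
        peak = max(peak, float(np.max(env.samples)))
    if not peak > 0:
        raise DegenerateMVCError("MVC trials contain no signal (peak envelope is 0)")
    return peak


def normalize_mvc(u: EMGTrace, mvc_value: float) -> EMGTrace:
    """Divide by the MVC envelope peak, clamping values above 1."""
    if not mvc_value > 0:
        raise ParameterError("mvc_value must be positive")
    return u.with_samples(np.minimum(u.samples / mvc_value, 1.0), u.stage)


def dead_band_rectify(a, dead_band: float = 0.02):
    """Staircase dead-band filter suppressing small activation changes.

    The output holds its previous value until the input moves away from it by
    more than ``dead_band`` relative to the held value; for held values below
    ``dead_band`` an absolute band of ``dead_band`` applies, which pins the
    relaxation state near zero.  Accepts an activation :class:`EMGTrace` or a
    plain array and returns the same type.  Idempotent.  ``dead_band = 0``
    disables the rectification (identity).
    """
    lo, hi = DEAD_BAND_RANGE
    if dead_band != 0.0 and not lo <= dead_band <= hi:
        raise ParameterError(f"dead_band must be 0 (off) or lie in [{lo}, {hi}]")
    is_trace = isinstance(a, EMGTrace)
    x = a.samples if is_trace else np.asarray(a, dtype=float)
    if dead_band == 0.0:
        return a.with_samples(x.copy(), a.stage) if is_trace else x.copy()
    out = np.empty_like(x)
    held = x[0]
    out[0] = held
    for i in range(1, x.size):
        band = dead_band * held if held >= dead_band else dead_band
        if abs(x[i] - held) > band:
            held = x[i]
        out[i] = held
    if is_trace:
        return a.with_samples(out, a.stage)
    return out
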