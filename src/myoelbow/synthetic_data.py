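"""Synthetic surface-EMG generator with ground-truth elbow angles.

Real recordings are not required to exercise the estimation chain: this
module produces raw EMG surrogates whose statistical structure matches what
the method assumes.

The forward model runs trajectory -> activation envelope -> raw EMG:

* the *trajectory* is the scripted movement (trapezoid to 90 deg at 30 deg/s
  with a 3 s hold, or a staircase of fixed increments with 3 s holds);
* the *envelope* is the inverse of a known monotone quadratic map from
  activation to cos^2(theta), multiplied during rising-angle samples by an
  overshoot factor (concentric contraction demands more force than the
  isometric hold — the extra inertial torque) that relaxes back with a
  150 ms time constant once the ramp ends; the envelope leads the angle by
  the electromechanical delay, as real EMG precedes motion;
* the *raw EMG* is the standard surface-EMG interference surrogate:
  band-limited (20-450 Hz) zero-mean Gaussian noise amplitude-modulated by
  the envelope, with an additional slow (2 Hz) multiplicative jitter.

Everything is reproducible from a single integer seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np
from scipy import signal

from .emg_processing import EMGTrace
from .exceptions import ParameterError

__all__ = [
    "SyntheticSubject",
    "TrajectorySpec",
    "make_trajectory",
    "trajectory_to_envelope",
    "envelope_to_raw_emg",
    "make_mvc_envelope",
    "generate_dataset",
]

#: overshoot relaxation time constant (s); transition effects at the
#: flexion-to-holding boundary play out over roughly 100-200 ms
OVERSHOOT_TAU_S = 0.15

#: angular-velocity threshold (deg/s) above which a sample counts as rising
_RISING_EPS = 1e-6



@dataclass(frozen=True)
class SyntheticSubject:
    """Forward-model parameters of one simulated subject.

    ``true_poly`` are ascending coefficients of the monotone decreasing
    quadratic activation -> cos^2(theta) map; the default reaches
    cos^2 = 0 (theta = 90 deg) at an activation of about 0.57, i.e. holding
    the horizontal forearm demands well below maximal drive, which leaves
    headroom for the flexion overshoot.  ``overshoot_factor`` multiplies the
    envelope while the angle rises.  ``mvc_scale`` is the raw amplitude at
    full activation, ``noise_band`` the carrier band in Hz,
    ``envelope_jitter`` the relative s.d. of the slow multiplicative
    envelope noise, and ``emd_lead_s`` the electromechanical lead of the
    envelope over the angle.
    """

    true_poly: Tuple[float, float, float] = (1.0, -2.2, 0.8)
    overshoot_factor: float = 1.15
    mvc_scale: float = 1.0
    noise_band: Tuple[float, float] = (20.0, 450.0)
    envelope_jitter: float = 0.05
    emd_lead_s: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.overshoot_factor < 1:
            raise ParameterError("overshoot_factor must be >= 1")
        if self.envelope_jitter < 0 or self.mvc_scale <= 0:
            raise ParameterError("mvc_scale must be positive, jitter non-negative")
        if not 0 < self.noise_band[0] < self.noise_band[1]:
            raise ParameterError("noise_band must be an increasing positive pair")
        if self.emd_lead_s < 0:
            raise ParameterError("emd_lead_s must be non-negative")


@dataclass(frozen=True)
class TrajectorySpec:
    """Scripted elbow movement: continuous trapezoid or consecutive steps."""

    kind: str = "continuous"
    ramp_rate: float = 30.0
    hold_s: float = 3.0
    step_increment: float = 30.0
    peak_deg: float = 90.0
    rest_s: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("continuous", "stepping"):
            raise ParameterError("kind must be 'continuous' or 'stepping'")
        if not 0 < self.peak_deg <= 90:
            raise ParameterError("peak_deg must lie in (0, 90]")
        if not self.ramp_rate > 0:
            raise ParameterError("ramp_rate must be positive")
        if self.hold_s < 0 or self.rest_s < 0:
            raise ParameterError("hold_s and rest_s must be non-negative")
        if self.kind == "stepping" and not self.step_increment > 0:
            raise ParameterError("step_increment must be positive")


def _breakpoints(spec: TrajectorySpec) -> Tuple[np.ndarray, np.ndarray]:
    t, v = [0.0], [0.0]

    def add(dt: float, value: float) -> None:
        if dt > 0:
            t.append(t[-1] + dt)
            v.append(value)

    add(spec.rest_s, 0.0)
    if spec.kind == "continuous":
        add(spec.peak_deg / spec.ramp_rate, spec.peak_deg)
        add(spec.hold_s, spec.peak_deg)
        add(spec.peak_deg / spec.ramp_rate, 0.0)
    else:
        n_full = int(spec.peak_deg // spec.step_increment)
        rises = [spec.step_increment] * n_full
        rem = spec.peak_deg - n_full * spec.step_increment
        if rem > 1e-9:
            warnings.warn(
                "step_increment does not divide peak_deg; last step truncated "
                f"to {rem:g} deg",
                stacklevel=3,
            )
            rises.append(rem)
        level = 0.0
        for inc in rises:
            level += inc
            add(inc / spec.ramp_rate, level)
            add(spec.hold_s, level)
        for inc in reversed(rises):
            level -= inc
            add(inc / spec.ramp_rate, level)
            add(spec.hold_s, level)
    add(spec.rest_s, 0.0)
    return np.asarray(t), np.asarray(v)


def make_trajectory(spec: TrajectorySpec, sampling_rate: float) -> np.ndarray:
    """Piecewise-linear ground-truth angle series (degrees), start/end at 0."""
    bp_t, bp_v = _breakpoints(spec)
    n = int(round(bp_t[-1] * sampling_rate))
    t = np.arange(n) / sampling_rate
    return np.interp(t, bp_t, bp_v)


def _invert_true_poly(subject: SyntheticSubject, y: np.ndarray) -> np.ndarray:
    """Exact inverse of the monotone decreasing quadratic map at cos^2 = y.

    Solves ``c2*a^2 + c1*a + (c0 - y) = 0`` on the branch through a = 0
    (stable form avoiding cancellation); targets below the reachable minimum
    of the map are clamped to the vertex.
    """
    c0, c1, c2 = subject.true_poly
    if c1 >= 0:
        raise ParameterError("true_poly must be monotone decreasing from a = 0")
    delta = c0 - np.asarray(y, dtype=float)
    disc = np.maximum(c1 * c1 - 4.0 * c2 * delta, 0.0)
    return 2.0 * delta / (-c1 + np.sqrt(disc))


def trajectory_to_envelope(
    angles_deg: np.ndarray, subject: SyntheticSubject, sampling_rate: float
) -> np.ndarray:
    """Activation envelope in [0, 1] for a ground-truth angle series.

    The base envelope is the exact inverse of ``true_poly`` at
    cos^2(theta); rising-angle samples carry the multiplicative overshoot,
    which decays exponentially (tau = 150 ms) once the angle stops rising.
    The result is shifted earlier by the subject's electromechanical lead.
    """
    theta = np.asarray(angles_deg, dtype=float)
    if np.any(theta < 0) or np.any(theta > 90):
        raise ParameterError("angles must lie in [0, 90] degrees")
    cos2 = np.cos(np.radians(theta)) ** 2
    base = _invert_true_poly(subject, cos2)

    rising = np.gradient(theta) * sampling_rate > _RISING_EPS
    decay = np.exp(-1.0 / (OVERSHOOT_TAU_S * sampling_rate))
    m = np.ones(theta.size)
    prev = 1.0
    for i in range(theta.size):
        if rising[i]:
            prev = subject.overshoot_factor
        else:
            prev = 1.0 + (prev - 1.0) * decay
        m[i] = prev
    envelope = np.clip(m * base, 0.0, 1.0)

    lead = int(round(subject.emd_lead_s * sampling_rate))
    if lead > 0 and lead < envelope.size:
        envelope = np.concatenate([envelope[lead:], np.full(lead, envelope[-1])])
    return envelope


def _unit_noise(
    n: int, rng: np.random.Generator, sos: np.ndarray
) -> np.ndarray:
    x = signal.sosfilt(sos, rng.standard_normal(n))
    sd = x.std()
    return x / sd if sd > 0 else x


def envelope_to_raw_emg(
    envelope: np.ndarray,
    subject: SyntheticSubject,
    sampling_rate: float,
    rng: Optional[np.random.Generator] = None,
) -> EMGTrace:
    """Amplitude-modulated band-limited Gaussian raw EMG surrogate.

    ``raw(t) = mvc_scale * envelope(t) * (1 + jitter(t)) * n(t)`` with n a
    unit-variance carrier band-passed to ``noise_band`` and jitter a slow
    (2 Hz low-passed) Gaussian of relative s.d. ``envelope_jitter``.
    Bit-reproducible for a given generator.
    """
    envelope = np.asarray(envelope, dtype=float)
    if np.any(envelope < 0) or np.any(envelope > 1):
        raise ParameterError("envelope must lie in [0, 1]")
    nyquist = sampling_rate / 2.0
    lo, hi = subject.noise_band
    if hi >= nyquist:
        raise ParameterError("noise_band upper edge must be below Nyquist")
    if rng is None:
        rng = np.random.default_rng(subject.seed)
    n = envelope.size
    sos_carrier = signal.butter(
        4, [lo, hi], btype="bandpass", fs=sampling_rate, output="sos"
    )
    carrier = _unit_noise(n, rng, sos_carrier)
    if subject.envelope_jitter > 0:
        sos_jitter = signal.butter(2, 2.0, btype="lowpass", fs=sampling_rate, output="sos")
        jitter = subject.envelope_jitter * _unit_noise(n, rng, sos_jitter)
    else:
        jitter = np.zeros(n)
    modulated = subject.mvc_scale * envelope * np.maximum(1.0 + jitter, 0.0) * carrier
    return EMGTrace(modulated, sampling_rate, "raw")


def make_mvc_envelope(sampling_rate: float, duration_s: float = 3.0) -> np.ndarray:
    """Full-drive envelope for a maximum-voluntary-contraction trial."""
    return np.ones(int(round(duration_s * sampling_rate)))


def generate_dataset(
    spec: TrajectorySpec,
    subject: SyntheticSubject,
    n_trials: int,
    seed: Optional[int] = None,
    sampling_rate: float = 1000.0,
) -> Tuple[List[Tuple[EMGTrace, np.ndarray]], EMGTrace]:
    """Generate ``n_trials`` (raw EMG, ground-truth angle) pairs plus one MVC trial.

    Per-trial seeds derive deterministically from ``seed`` (defaults to the
    subject's seed), so identical inputs give identical datasets while the
    carrier noise is independent across trials.  The ground-truth angle
    series is the same deterministic trajectory in every trial.
    """
    if n_trials < 1:
        raise ParameterError("n_trials must be >= 1")
    if seed is None:
        seed = subject.seed
    angles = make_trajectory(spec, sampling_rate)
    envelope = trajectory_to_envelope(angles, subject, sampling_rate)
    children = np.random.SeedSequence(seed).spawn(n_trials + 1)
    trials = []
    for i in range(n_trials):
        rng = np.random.default_rng(children[i])
        raw = envelope_to_raw_emg(envelope, subject, sampling_rate, rng)
        trials.append((raw, angles.copy()))
    mvc_rng = np.random.default_rng(children[n_trials])
    mvc = envelope_to_raw_emg(
        make_mvc_envelope(sampling_rate), subject, sampling_rate, mvc_rng
    )
    return trials, mvc
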