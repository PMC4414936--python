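"""Hill-type muscle-model primitives for the elbow flexor.

The contractile element produces ``F_CE = F_max * a * f_l * f_v`` where
``f_l`` is a Gaussian force-length curve peaking at a normalized length
change of 0.05 and ``f_v`` a sigmoidal force-velocity curve.  With the
tendon assumed rigid, the elbow geometry reduces the length change of the
contractile element to ``dL_CE = alpha * L_CE0 * cos(theta)`` and the
normalized shortening velocity to ``V_CE/V_CE0 = -0.1*alpha*dtheta*sin(theta)``
(dtheta in rad/s), with the maximum contraction velocity taken as
``10 L_CE0/s`` for upper-limb muscles.

Composing these relations with the exponential activation nonlinearity and
taking logarithms yields, after dropping the near-unity force-velocity term
and the small inertial torque, a quadratic relationship between ``cos^2(theta)``
and the scaled activation ``a/R`` — the structure the calibration module fits
per subject.  The lumped constants of that derivation (forearm mass, inertia,
moment arms) are absorbed into the fitted polynomial and never estimated
individually.

Angle convention: theta = 0 deg at full extension (forearm vertical,
relaxed), theta = 90 deg with the forearm horizontal, so cos(theta) falls
from 1 to 0 during flexion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence, Union

import numpy as np

from .exceptions import ParameterError

__all__ = [
    "HillParameters",
    "JointState",
    "passive_force",
    "force_length",
    "force_velocity",
    "vce0",
    "contractile_force",
    "total_force",
    "quadratic_model_value",
]

#: |sinh argument| beyond which force_velocity returns its analytic
#: asymptote; at |arg| = 6.5, sinh exceeds 300 and the exponential term is
#: already 0 or overflowing in double precision
_SINH_GUARD = 6.5

ArrayLike = Union[float, np.ndarray]


@dataclass(frozen=True)
class HillParameters:
    """Muscle and geometry constants of the Hill-type flexor model.

    Attributes
    ----------
    F_max
        Maximum isometric force (N).
    L_CE0
        Optimal contractile-element length (m).
    V_CE_max
        Maximum contraction velocity in units of L_CE0 per second
        (10 is the standard upper-limb value).
    alpha_ratio
        Ratio of the tendon-insertion distance l to the forearm-centroid
        distance L; sets the moment-arm geometry.
    S
        Passive-element exponential shape parameter.
    dL_max
        Passive-element length change (m) at which it exerts its
        characteristic force.
    """

    F_max: float = 300.0
    L_CE0: float = 0.12
    V_CE_max: float = 10.0
    alpha_ratio: float = 0.1
    S: float = 1.0
    dL_max: float = 0.05

    def __post_init__(self) -> None:
        if not (self.F_max > 0 and self.L_CE0 > 0 and self.V_CE_max > 0):
            raise ParameterError("F_max, L_CE0 and V_CE_max must be positive")
        if not 0 < self.alpha_ratio < 1:
            raise ParameterError("alpha_ratio must lie in (0, 1)")
        if self.S == 0:
            raise ParameterError("S must be nonzero")
        if not self.dL_max > 0:
            raise ParameterError("dL_max must be positive")


@dataclass(frozen=True)
class JointState:
    """Elbow kinematic state in degrees (0 = fully extended, 90 = horizontal)."""

    theta: float
    dtheta: float = 0.0
    ddtheta: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.theta <= 90.0:
            raise ParameterError("theta must lie in [0, 90] degrees")


def passive_force(delta_L: ArrayLike, params: HillParameters) -> ArrayLike:
    """Passive exponential force of the parallel/series element.

    ``F = (F_max/e^S - 1) * (exp((S/dL_max)*dL) - 1)``; zero at zero length
    change.  The elbow pipeline runs with the passive contribution wired to
    zero (rigid tendon, relaxed parallel element), but the primitive is kept
    for completeness.
    """
    scale = params.F_max / math.exp(params.S) - 1.0
    return scale * np.expm1((params.S / params.dL_max) * np.asarray(delta_L, float))


def force_length(delta_L_CE: ArrayLike, L_CE0: float) -> ArrayLike:
    """Gaussian force-length factor, maximal (=1) at dL_CE/L_CE0 = 0.05."""
    if not L_CE0 > 0:
        raise ParameterError("L_CE0 must be positive")
    z = (np.asarray(delta_L_CE, float) / L_CE0 - 0.05) / 0.19
    return np.exp(-0.5 * z * z)


def force_velocity(v_ratio: ArrayLike) -> ArrayLike:
    """Sigmoidal force-velocity factor of normalized velocity V_CE/V_CE0.

    ``f_v = 0.1433 / (0.1074 + exp(-1.3*sinh(2.8*v + 1.64)))``; monotone
    increasing, tending to 0 for fast lengthening-convention negative
    velocities and to 0.1433/0.1074 ~ 1.334 for fast shortening.  The sinh
    argument is guarded so extreme inputs return the analytic asymptote
    instead of overflowing.
    """
    v = np.asarray(v_ratio, dtype=float)
    arg = 2.8 * v + 1.64
    out = np.empty_like(arg)
    hi = arg > _SINH_GUARD
    lo = arg < -_SINH_GUARD
    mid = ~(hi | lo)
    out[hi] = 0.1433 / 0.1074
    out[lo] = 0.0
    out[mid] = 0.1433 / (0.1074 + np.exp(-1.3 * np.sinh(arg[mid])))
    if np.isscalar(v_ratio):
        return float(out)
    return out


def vce0(a: float, params: HillParameters) -> float:
    """Activation-dependent velocity scale ``V_CE0 = 0.5*(a + 1)*V_CE_max``."""
    if not 0.0 <= a <= 1.0:
        raise ParameterError("activation must lie in [0, 1]")
    return 0.5 * (a + 1.0) * params.V_CE_max


def contractile_force(
    a: float, state: JointState, params: HillParameters
) -> float:
    """Contractile-element force for a given activation and joint state.

    Uses the reduced geometry ``dL_CE = alpha*L_CE0*cos(theta)`` and
    ``V_CE/V_CE0 = -0.1*alpha*dtheta*sin(theta)`` with dtheta converted to
    rad/s (the time derivative of l*cos(theta) requires radians).
    """
    if not 0.0 <= a <= 1.0:
        raise ParameterError("activation must lie in [0, 1]")
    theta_rad = math.radians(state.theta)
    dtheta_rad = math.radians(state.dtheta)
    delta_l_ce = params.alpha_ratio * params.L_CE0 * math.cos(theta_rad)
    f_l = float(force_length(delta_l_ce, params.L_CE0))
    v_ratio = -0.1 * params.alpha_ratio * dtheta_rad * math.sin(theta_rad)
    f_v = float(force_velocity(v_ratio))
    return params.F_max * a * f_l * f_v


def total_force(F_CE: float, F_PE: float) -> float:
    """Total muscle force ``F_T = F_CE + F_PE``."""
    if not (np.isfinite(F_CE) and np.isfinite(F_PE)):
        raise ParameterError("forces must be finite")
    return F_CE + F_PE


def quadratic_model_value(
    a: ArrayLike, coefficients: Sequence[float], R: float
) -> ArrayLike:
    """Evaluate the quadratic surrogate ``sum_i c_i * (a/R)**i`` (i = 0..2).

    This is the right-hand structure the calibration module fits against
    cos^2(theta); the lumped musculoskeletal constants live inside the
    coefficients.
    """
    if len(coefficients) != 3:
        raise ParameterError("quadratic model needs exactly three coefficients")
    x = np.asarray(a, dtype=float) / R
    c0, c1, c2 = coefficients
    out = c0 + c1 * x + c2 * x * x
    if np.isscalar(a):
        return float(out)
    return out
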