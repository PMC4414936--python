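"""Tracking-accuracy metrics for predicted versus recorded elbow angles."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np

from .exceptions import ParameterError

__all__ = ["EvaluationReport", "rms_error", "correlation", "evaluate"]


@dataclass(frozen=True)
class EvaluationReport:
    """Summary of prediction quality for one trial.

    ``rms_error`` and ``per_state_rms`` are in degrees, ``correlation`` is
    the Pearson r between predicted and recorded angles, and
    ``lag_estimate`` the cross-correlation-peak lag in seconds (positive
    when the prediction trails the recording).
    """

    rms_error: float
    correlation: float
    per_state_rms: Dict[str, float] = field(default_factory=dict)
    lag_estimate: float = 0.0

    def __post_init__(self) -> None:
        if self.rms_error < 0 or not -1.0 <= self.correlation <= 1.0 + 1e-12:
            raise ParameterError("invalid report values")

    def to_dict(self) -> dict:
        return {
            "rms_error_deg": self.rms_error,
            "correlation": self.correlation,
            "per_state_rms_deg": dict(self.per_state_rms),
            "lag_estimate_s": self.lag_estimate,
        }


def _paired(pred, truth):
    pred = np.asarray(pred, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if pred.shape != truth.shape or pred.size < 1:
        raise ParameterError("pred and truth must be equal-length, non-empty")
    return pred, truth


def rms_error(pred, truth) -> float:
    """Root-mean-square deviation, in the units of the inputs (degrees)."""
    pred, truth = _paired(pred, truth)
    return float(np.sqrt(np.mean((pred - truth) ** 2)))


def correlation(pred, truth) -> float:
    """Pearson correlation; errors out when either series is constant."""
    pred, truth = _paired(pred, truth)
    if np.ptp(pred) == 0 or np.ptp(truth) == 0:
        raise ParameterError("correlation undefined for a zero-variance series")
    return float(np.corrcoef(pred, truth)[0, 1])


def lag_seconds(pred, truth, sampling_rate: float) -> float:
    """Cross-correlation-peak lag of pred behind truth, in seconds."""
    pred, truth = _paired(pred, truth)
    p = pred - pred.mean()
    t = truth - truth.mean()
    xc = np.correlate(p, t, mode="full")
    return float((np.argmax(xc) - (pred.size - 1)) / sampling_rate)


def evaluate(
    pred,
    truth,
    sampling_rate: float,
    states: Optional[np.ndarray] = None,
) -> EvaluationReport:
    """Build a full :class:`EvaluationReport` for one predicted trial."""
    per_state: Dict[str, float] = {}
    if states is not None:
        states = np.asarray(states)
        pred_a, truth_a = _paired(pred, truth)
        for name in np.unique(states):
            mask = states == name
            per_state[str(name)] = rms_error(pred_a[mask], truth_a[mask])
    return EvaluationReport(
        rms_error=rms_error(pred, truth),
        correlation=correlation(pred, truth),
        per_state_rms=per_state,
        lag_estimate=lag_seconds(pred, truth, sampling_rate),
    )
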