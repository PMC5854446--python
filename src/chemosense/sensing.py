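"""Temporal and spatial sensing output functionals and the strategy decision.

A temporally sensing cell integrates the deviation of its mean output from
the pre-gradient baseline; a spatially sensing cell integrates the
front-to-back imbalance of the output.  Whichever functional is larger (via
the ratio O_TS = O_T / O_S) is the favored strategy; if neither is
positive, sensing has failed outright.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .ring import RingGrid, SpatialTrajectory

__all__ = [
    "Decision",
    "SensingOutputs",
    "temporal_output",
    "spatial_output",
    "output_ratio",
    "decide",
    "evaluate_trajectory",
]


class Decision(str, Enum):
    TEMPORAL = "temporal"
    SPATIAL = "spatial"
    FAILURE = "failure"


@dataclass(frozen=True)
class SensingOutputs:
    O_T: float
    O_S: float
    O_TS: float | None  # None when the ratio is not meaningful
    decision: Decision

    def to_dict(self) -> dict:
        return {"O_T": self.O_T, "O_S": self.O_S, "O_TS": self.O_TS,
                "decision": self.decision.value}


def temporal_output(traj: SpatialTrajectory) -> float:
    """O_T: time-integrated relative deviation of C from its baseline,
    averaged over compartments (trapezoidal rule on the stored times)."""
    base = traj.baseline_C
    if np.any(base <= 0):
        raise ValueError("temporal output undefined: zero baseline C")
    integrand = (traj.C / base - 1.0).sum(axis=1) / traj.grid.N
    return float(np.trapezoid(integrand, traj.times))


def spatial_output(traj: SpatialTrajectory,
                   grid: RingGrid | None = None) -> float:
    """O_S: time-integrated front-over-back output imbalance."""
    back = traj.back_C
    if np.any(back <= 0):
        raise ValueError("spatial output undefined: back half C reaches zero")
    integrand = traj.front_C / back - 1.0
    return float(np.trapezoid(integrand, traj.times))


def output_ratio(O_T: float, O_S: float) -> float | None:
    """O_TS = O_T / O_S, defined only when both outputs are positive."""
    if O_T > 0.0 and O_S > 0.0:
        return O_T / O_S
    return None


def decide(O_T: float, O_S: float) -> Decision:
    """Strategy choice: larger positive output wins; ties go to temporal;
    neither positive means sensing failure."""
    t_pos, s_pos = O_T > 0.0, O_S > 0.0
    if not t_pos and not s_pos:
        return Decision.FAILURE
    if t_pos and not s_pos:
        return Decision.TEMPORAL
    if s_pos and not t_pos:
        return Decision.SPATIAL
    return Decision.TEMPORAL if O_T / O_S >= 1.0 else Decision.SPATIAL


def evaluate_trajectory(traj: SpatialTrajectory) -> SensingOutputs:
    """Both functionals plus ratio and decision for one ring trajectory."""
    O_T = temporal_output(traj)
    O_S = spatial_output(traj)
    return SensingOutputs(O_T=O_T, O_S=O_S, O_TS=output_ratio(O_T, O_S),
                          decision=decide(O_T, O_S))
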