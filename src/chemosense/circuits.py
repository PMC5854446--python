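"""Well-mixed (point-cell) dynamics of the two adaptive three-node circuits.

Two network motifs are known to give near-perfect adaptation with three
nodes: negative integral feedback (NFB), where a buffer species B integrates
the deviation of the output C from its set point and feeds back to remove C,
and the incoherent feedforward loop (IFF), where the input activates both an
activator A and a repressor B that act oppositely on C.  The activated
fractions obey

    dA/dtau = k_IA * I - l_FA * A
    dB/dtau = k_CB * C - l_FB              (NFB; zero-order decay)
            = k_IB * I - l_FB * B          (IFF)
    dC/dtau = k_AC * A * (1-C)/(K_AC + 1-C) - l_BC * B * C/(L_BC + C)

in dimensionless time tau = t * l_BC, so ``l_BC == 1`` internally and every
other rate is a ratio to the physical deactivation rate of C.  The zero-order
decay of B in the NFB branch is what makes the feedback integral: at steady
state ``C* = l_FB / k_CB`` independent of the input.  B is clamped at zero
(its decay cannot drive it negative), and the (1-C) / C factors keep the
output fraction inside [0, 1].
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

__all__ = [
    "Topology",
    "CircuitParams",
    "CircuitState",
    "StepStimulus",
    "PointTrajectory",
    "NonAdaptiveParameters",
    "UndefinedMetric",
    "circuit_rhs",
    "steady_state",
    "simulate_point",
    "sensitivity",
    "precision",
]


class Topology(str, Enum):
    """Which adaptive motif wires B: integral feedback or feedforward."""

    NFB = "nfb"
    IFF = "iff"


class NonAdaptiveParameters(ValueError):
    """Raised when a parameter set has no admissible steady state."""


class UndefinedMetric(ValueError):
    """Raised when sensitivity/precision are not defined for a stimulus."""


@dataclass(frozen=True)
class CircuitParams:
    """Rate and equilibrium constants of one circuit instance.

    Rates are expressed relative to the output deactivation rate ``l_BC``
    (held at 1 in the dimensionless system).  ``k_IB`` only enters the IFF
    branch and ``k_CB`` only the NFB branch; the unused one may be left at
    its default.
    """

    k_IA: float = 1.0
    k_IB: float = 1.0
    k_CB: float = 1.0
    k_AC: float = 1.0
    l_FA: float = 1.0
    l_FB: float = 1.0
    K_AC: float = 0.1
    L_BC: float = 0.1
    l_BC: float = 1.0

    def __post_init__(self) -> None:
        for name in ("k_IA", "k_IB", "k_CB", "k_AC", "l_FA", "l_FB",
                     "K_AC", "L_BC", "l_BC"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be finite and > 0, got {v!r}")

    def replace_rates(self, **rates: float) -> "CircuitParams":
        from dataclasses import replace

        return replace(self, **rates)

    def to_dict(self) -> dict:
        return {
            "k_IA": self.k_IA, "k_IB": self.k_IB, "k_CB": self.k_CB,
            "k_AC": self.k_AC, "l_FA": self.l_FA, "l_FB": self.l_FB,
            "K_AC": self.K_AC, "L_BC": self.L_BC, "l_BC": self.l_BC,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CircuitParams":
        return cls(**{k: float(v) for k, v in d.items()
                      if k in cls.__dataclass_fields__})


@dataclass(frozen=True)
class CircuitState:
    """Activated fractions of the three species."""

    A: float
    B: float
    C: float

    def __post_init__(self) -> None:
        if not all(math.isfinite(x) for x in (self.A, self.B, self.C)):
            raise ValueError("non-finite circuit state")

    def as_array(self) -> np.ndarray:
        return np.array([self.A, self.B, self.C], dtype=float)


@dataclass(frozen=True)
class StepStimulus:
    """Step input: level I_L before tau_step, I_H from tau_step to tau_end."""

    I_L: float = 0.5
    I_H: float = 0.6
    tau_step: float = 0.0
    tau_end: float = 50.0

    def __post_init__(self) -> None:
        if self.I_L <= 0 or self.I_H < self.I_L:
            raise ValueError("require 0 < I_L <= I_H")
        if not self.tau_end > self.tau_step >= 0:
            raise ValueError("require tau_end > tau_step >= 0")

    def level(self, tau: float) -> float:
        return self.I_H if tau >= self.tau_step else self.I_L


def _dC(A, B, C, p: CircuitParams):
    """Output-node kinetics shared by both topologies (array-safe)."""
    production = p.k_AC * A * (1.0 - C) / (p.K_AC + 1.0 - C)
    removal = p.l_BC * B * C / (p.L_BC + C)
    return production - removal


def circuit_rhs(state: CircuitState | Sequence[float], input_level: float,
                params: CircuitParams, topology: Topology):
    """Time derivatives (dA, dB, dC) at one state and input level.

    The NFB branch reports dB = 0 when B is at its floor (B <= 0) and the
    raw zero-order decay would push it negative.
    """
    if isinstance(state, CircuitState):
        A, B, C = state.A, state.B, state.C
    else:
        A, B, C = state
    if not (np.isfinite(A) and np.isfinite(B) and np.isfinite(C)
            and np.isfinite(input_level)):
        raise ValueError("non-finite state or input")
    dA = params.k_IA * input_level - params.l_FA * A
    if topology is Topology.NFB:
        dB = params.k_CB * C - params.l_FB
        if B <= 0.0 and dB < 0.0:
            dB = 0.0
    else:
        dB = params.k_IB * input_level - params.l_FB * B
    return dA, dB, _dC(A, B, C, params)


def steady_state(params: CircuitParams, topology: Topology,
                 input_level: float) -> CircuitState:
    """Fixed point of the circuit at a constant input.

    NFB: ``C* = l_FB / k_CB`` analytically (input-independent); B* balances
    the C equation.  IFF: A* and B* are both proportional to the input, so
    the C nullcline — and hence C* — is input-independent; C* is found by
    bracketing root search on [0, 1].
    """
    if input_level <= 0:
        raise ValueError("input_level must be > 0")
    A_star = params.k_IA * input_level / params.l_FA
    if topology is Topology.NFB:
        C_star = params.l_FB / params.k_CB
        if not 0.0 < C_star < 1.0:
            raise NonAdaptiveParameters(
                f"NFB set point l_FB/k_CB = {C_star:.4g} outside (0, 1)")
        prod = params.k_AC * A_star * (1.0 - C_star) / (params.K_AC + 1.0 - C_star)
        B_star = prod * (params.L_BC + C_star) / (params.l_BC * C_star)
        return CircuitState(A_star, B_star, C_star)
    B_star = params.k_IB * input_level / params.l_FB

    def g(C: float) -> float:
        return _dC(A_star, B_star, C, params)

    # g is strictly decreasing on [0, 1] with g(0) > 0 > g(1).
    if not (g(0.0) > 0.0 and g(1.0) < 0.0):
        raise NonAdaptiveParameters("IFF output nullcline has no root in (0, 1)")
    C_star = brentq(g, 0.0, 1.0, xtol=1e-15, rtol=8.9e-16)
    return CircuitState(A_star, B_star, C_star)


@dataclass
class PointTrajectory:
    """Stored point-cell trajectory plus the step-response summary levels."""

    times: np.ndarray
    A: np.ndarray
    B: np.ndarray
    C: np.ndarray
    C_initial: float = field(default=np.nan)
    C_max: float = field(default=np.nan)
    C_final: float = field(default=np.nan)

    def __post_init__(self) -> None:
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")


def _step_t_eval(stimulus: StepStimulus, spacing: float = 0.05) -> np.ndarray:
    """Uniform output grid at the reference signaling resolution.

    The peak response is read off this grid, so the screen's sensitivity is
    measured at the same temporal resolution the sensing functionals use
    downstream; a transient living far below the signaling timescale is
    invisible to both and is not counted as a response.
    """
    t1 = stimulus.tau_end
    grid = np.linspace(0.0, t1, int(round(t1 / spacing)) + 1)
    return np.unique(np.concatenate([grid, [stimulus.tau_step, t1]]))


def simulate_point(params: CircuitParams, topology: Topology,
                   stimulus: StepStimulus, rtol: float = 1e-8,
                   atol: float = 1e-11) -> PointTrajectory:
    """Integrate a pre-equilibrated point cell through a step input.

    The initial condition is the steady state at I_L; the input switches to
    I_H at ``tau_step``.  Integration uses a stiff-capable adaptive method
    (LSODA); the switch time is a hard stop so the discontinuity is never
    stepped over.
    """
    y0 = steady_state(params, topology, stimulus.I_L).as_array()

    def rhs(tau, y):
        return circuit_rhs(y, stimulus.level(tau), params, topology)

    t_eval = _step_t_eval(stimulus)
    pieces = []
    if stimulus.tau_step > 0:
        pre = solve_ivp(rhs, (0.0, stimulus.tau_step), y0, method="LSODA",
                        rtol=rtol, atol=atol,
                        t_eval=t_eval[t_eval <= stimulus.tau_step])
        if not pre.success:
            raise RuntimeError(f"integration failed before step: {pre.message}")
        pieces.append(pre)
        y0 = pre.y[:, -1]
    post = solve_ivp(rhs, (stimulus.tau_step, stimulus.tau_end), y0,
                     method="LSODA", rtol=rtol, atol=atol,
                     t_eval=t_eval[t_eval >= stimulus.tau_step])
    if not post.success:
        raise RuntimeError(
            f"integration failed for {params.to_dict()}: {post.message}")
    if pieces:
        times = np.concatenate([pieces[0].t, post.t])
        Y = np.concatenate([pieces[0].y, post.y], axis=1)
        times, idx = np.unique(times, return_index=True)
        Y = Y[:, idx]
    else:
        times, Y = post.t, post.y
    A, B, C = Y
    C_initial = float(steady_state(params, topology, stimulus.I_L).C)
    after = times > stimulus.tau_step
    C_max = float(np.max(C[after])) if np.any(after) else C_initial
    traj = PointTrajectory(times=times, A=A, B=np.maximum(B, 0.0), C=C,
                           C_initial=C_initial, C_max=C_max,
                           C_final=float(C[-1]))
    return traj


def sensitivity(traj: PointTrajectory, stimulus: StepStimulus) -> float:
    """Normalized peak response: relative rise of C over relative input rise."""
    if stimulus.I_H == stimulus.I_L:
        raise UndefinedMetric("sensitivity undefined for a null step")
    if traj.C_initial <= 0:
        raise UndefinedMetric("sensitivity undefined for zero baseline")
    rel_out = (traj.C_max - traj.C_initial) / traj.C_initial
    rel_in = (stimulus.I_H - stimulus.I_L) / stimulus.I_L
    return max(rel_out, 0.0) / rel_in


def precision(traj: PointTrajectory, stimulus: StepStimulus) -> float:
    """Adaptation precision; +inf when C returns exactly to its baseline."""
    if stimulus.I_H == stimulus.I_L:
        raise UndefinedMetric("precision undefined for a null step")
    rel_in = (stimulus.I_H - stimulus.I_L) / stimulus.I_L
    drift = abs(traj.C_final - traj.C_initial)
    if drift == 0.0:
        return math.inf
    return (traj.C_initial / drift) / (1.0 / rel_in)
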