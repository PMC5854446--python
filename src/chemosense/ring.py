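"""Reaction-diffusion dynamics of the circuit on a moving one-dimensional ring cell.

The cell membrane is a ring of diameter d discretized into N equal
compartments.  Each compartment carries its own copy of the adaptive
circuit; A, B and C additionally diffuse along the ring.  The cell moves at
constant speed through a one-dimensional chemoattractant field, so the
input seen by compartment i is the field evaluated at its instantaneous
axial position.  Everything is dimensionless: lengths in units of the cell
diameter d, time in units of 1/l_BC, so the physics enters only through

    beta  = v / (d * l_BC)        cell speed over (diameter x signaling rate)
    alpha = v * k / l_BC          rate of input change seen by the moving cell
    D'_X  = D_X / (d^2 * l_BC)    dimensionless diffusivities

The gradient region starts at axial coordinate x' = 0 and has length
beta * T_s (the cell center crosses it in exactly T_s); beyond it the field
is flat at the plateau level I_H.  At tau = 0 the cell center sits at
x' = 0, i.e. the front half has already entered the gradient.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Protocol

import numpy as np
from scipy.integrate import solve_ivp
from scipy.linalg import expm

from .circuits import CircuitParams, Topology, steady_state

__all__ = [
    "RingGrid",
    "GradientShape",
    "GradientProfile",
    "DimensionlessTransport",
    "SpatialTrajectory",
    "NoiseHooks",
    "input_profile",
    "ring_laplacian",
    "simulate_ring",
    "summarize_traj",
]


@dataclass(frozen=True)
class RingGrid:
    """Equal-arclength compartments on a ring of (dimensionless) diameter 1.

    Angles are offset by half a compartment so no compartment center sits
    exactly on the front/back dividing plane: the front and back halves
    each contain exactly N/2 compartments.
    """

    N: int = 20

    def __post_init__(self) -> None:
        if self.N < 4 or self.N % 2:
            raise ValueError("N must be even and >= 4")

    @property
    def angles(self) -> np.ndarray:
        return 2.0 * np.pi * (np.arange(self.N) + 0.5) / self.N

    @property
    def axial_offsets(self) -> np.ndarray:
        """Position of each compartment along the motion axis, in [-1/2, 1/2]."""
        return np.cos(self.angles) / 2.0

    @property
    def spacing(self) -> float:
        """Arclength between neighbours: circumference pi over N."""
        return np.pi / self.N

    @property
    def front_mask(self) -> np.ndarray:
        return self.axial_offsets > 0

    @property
    def back_mask(self) -> np.ndarray:
        return self.axial_offsets < 0


class GradientShape(str, Enum):
    LINEAR = "linear"
    EXPONENTIAL = "exponential"
    STEP = "step"


@dataclass(frozen=True)
class GradientProfile:
    """Chemoattractant field along the motion axis.

    ``alpha`` sets the slope experienced by the moving cell; the exposure
    time T_s fixes the gradient region length beta * T_s.  The exponential
    shape is parameterized so its initial logarithmic slope matches the
    linear shape's relative slope at the baseline.  For a step the plateau
    I_H is given directly and alpha is unused.
    """

    shape: GradientShape = GradientShape.LINEAR
    I_L: float = 0.5
    alpha: float = 0.001
    T_s: float = 10.0
    I_H_step: float | None = None

    def __post_init__(self) -> None:
        if self.I_L <= 0:
            raise ValueError("I_L must be > 0")
        if self.T_s <= 0:
            raise ValueError("T_s must be > 0")
        if self.shape is GradientShape.STEP and (
                self.I_H_step is None or self.I_H_step <= self.I_L):
            raise ValueError("step profile needs I_H_step > I_L")

    @property
    def I_H(self) -> float:
        """Plateau level past the gradient region."""
        if self.shape is GradientShape.LINEAR:
            return self.I_L + self.alpha * self.T_s
        if self.shape is GradientShape.EXPONENTIAL:
            return self.I_L * math.exp(self.alpha * self.T_s / self.I_L)
        return float(self.I_H_step)

    def field_at(self, x: np.ndarray, beta: float) -> np.ndarray:
        """Evaluate the chemoattractant field at axial coordinates x."""
        if self.shape is GradientShape.STEP:
            return np.where(x < 0.0, self.I_L, self.I_H)
        span = beta * self.T_s
        xc = np.clip(x, 0.0, span)
        if self.shape is GradientShape.LINEAR:
            return self.I_L + (self.alpha / beta) * xc
        return self.I_L * np.exp((self.alpha / (beta * self.I_L)) * xc)


@dataclass(frozen=True)
class DimensionlessTransport:
    """Dimensionless speed group beta and diffusivities of the three species."""

    beta: float = 0.125
    D_A: float = 1.0
    D_B: float = 1.0
    D_C: float = 0.0

    def __post_init__(self) -> None:
        if not (math.isfinite(self.beta) and self.beta > 0):
            raise ValueError("beta must be finite and > 0")
        for name in ("D_A", "D_B", "D_C"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v >= 0):
                raise ValueError(f"{name} must be finite and >= 0")


class NoiseHooks(Protocol):
    """Per-step perturbations applied by the fixed-step integrator."""

    def modify_input(self, tau: float, x: np.ndarray,
                     I_det: np.ndarray) -> np.ndarray: ...

    def params_at(self, tau: float, base: CircuitParams) -> CircuitParams: ...


def input_profile(profile: GradientProfile, tau: float, grid: RingGrid,
                  beta: float) -> np.ndarray:
    """Deterministic input per compartment at time tau (cell center at beta*tau)."""
    x = beta * tau + grid.axial_offsets
    return profile.field_at(x, beta)


def ring_laplacian(values: np.ndarray, D_prime: float,
                   grid: RingGrid) -> np.ndarray:
    """Periodic second-difference operator scaled by D'/spacing^2."""
    if D_prime < 0:
        raise ValueError("D_prime must be >= 0")
    v = np.asarray(values, dtype=float)
    lap = np.roll(v, 1, axis=-1) - 2.0 * v + np.roll(v, -1, axis=-1)
    return (D_prime / grid.spacing ** 2) * lap


def _laplacian_matrix(grid: RingGrid) -> np.ndarray:
    N = grid.N
    L = -2.0 * np.eye(N) + np.eye(N, k=1) + np.eye(N, k=-1)
    L[0, -1] = L[-1, 0] = 1.0
    return L / grid.spacing ** 2


@dataclass
class SpatialTrajectory:
    """Ring trajectory: time x compartment arrays plus the uniform baseline."""

    times: np.ndarray
    A: np.ndarray
    B: np.ndarray
    C: np.ndarray
    grid: RingGrid
    baseline_C: np.ndarray  # per-compartment C at tau = 0

    @property
    def mean_C(self) -> np.ndarray:
        return self.C.mean(axis=1)

    @property
    def front_C(self) -> np.ndarray:
        return self.C[:, self.grid.front_mask].sum(axis=1)

    @property
    def back_C(self) -> np.ndarray:
        return self.C[:, self.grid.back_mask].sum(axis=1)


def summarize_traj(traj: SpatialTrajectory, grid: RingGrid | None = None):
    """(mean_C, front_C, back_C) series; front/back are sums over the halves."""
    return traj.mean_C, traj.front_C, traj.back_C


def _reaction_rhs(tau, A, B, C, I, p: CircuitParams, topology: Topology):
    dA = p.k_IA * I - p.l_FA * A
    if topology is Topology.NFB:
        dB = p.k_CB * C - p.l_FB
        dB = np.where((B <= 0.0) & (dB < 0.0), 0.0, dB)
    else:
        dB = p.k_IB * I - p.l_FB * B
    prod = p.k_AC * A * (1.0 - C) / (p.K_AC + 1.0 - C)
    rem = p.l_BC * B * C / (p.L_BC + C)
    return dA, dB, prod - rem


def _simulate_adaptive(params, topology, transport, profile, grid, tau_end,
                       rtol, atol, t_eval):
    N = grid.N
    ss = steady_state(params, topology, profile.I_L)
    y0 = np.concatenate([np.full(N, ss.A), np.full(N, ss.B), np.full(N, ss.C)])
    dA_coef = transport.D_A / grid.spacing ** 2
    dB_coef = transport.D_B / grid.spacing ** 2
    dC_coef = transport.D_C / grid.spacing ** 2
    beta = transport.beta
    offs = grid.axial_offsets

    def rhs(tau, y):
        A, B, C = y[:N], y[N:2 * N], y[2 * N:]
        I = profile.field_at(beta * tau + offs, beta)
        dA, dB, dC = _reaction_rhs(tau, A, B, C, I, params, topology)
        for arr, dst, coef in ((A, dA, dA_coef), (B, dB, dB_coef),
                               (C, dC, dC_coef)):
            if coef:
                dst += coef * (np.roll(arr, 1) - 2.0 * arr + np.roll(arr, -1))
        return np.concatenate([dA, dB, dC])

    sol = solve_ivp(rhs, (0.0, tau_end), y0, method="LSODA", rtol=rtol,
                    atol=atol, t_eval=t_eval)
    if not sol.success:
        raise RuntimeError(
            f"ring integration failed (beta={beta}, D_A={transport.D_A}, "
            f"D_B={transport.D_B}) for {params.to_dict()}: {sol.message}")
    Y = sol.y.T  # time x (3N)
    return SpatialTrajectory(times=sol.t, A=Y[:, :N], B=Y[:, N:2 * N],
                             C=Y[:, 2 * N:], grid=grid,
                             baseline_C=np.full(N, ss.C))


def _reaction_step(A, B, C, I, h, p: CircuitParams, topology: Topology):
    """One exponential-Euler reaction update of length h (in place).

    A (and B in the feedforward branch) relax linearly toward their
    input-set equilibria, so those updates are exact for input frozen over
    the step.  The output node is advanced by exponential Euler on its
    local linearization, which is L-stable: arbitrarily fast C relaxation
    (small Hill constants, large rates) cannot destabilize the step.  The
    zero-order decay of B in the feedback branch is integrated explicitly
    (it is never stiff) with the clamp at zero.
    """
    C_old = C.copy()
    # output node: dC = f(C), lam = -df/dC > 0 near any stable branch
    Cc = np.clip(C, 0.0, 1.0)
    prod = p.k_AC * A * (1.0 - Cc) / (p.K_AC + 1.0 - Cc)
    rem = p.l_BC * B * Cc / (p.L_BC + Cc)
    f = prod - rem
    lam = (p.k_AC * A * p.K_AC / (p.K_AC + 1.0 - Cc) ** 2
           + p.l_BC * B * p.L_BC / (p.L_BC + Cc) ** 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        phi = np.where(lam * h > 1e-8,
                       -np.expm1(-lam * h) / np.maximum(lam, 1e-300), h)
    C += f * phi
    np.clip(C, 0.0, 1.0, out=C)
    if topology is Topology.NFB:
        B += h * (p.k_CB * 0.5 * (C_old + C) - p.l_FB)
        np.maximum(B, 0.0, out=B)
    else:
        _linear_relax(B, p.k_IB * I, p.l_FB, h)
    _linear_relax(A, p.k_IA * I, p.l_FA, h)


def _linear_relax(X, source, l, h):
    """Exact update of dX = source - l*X over h (in place); ``l`` may be 0
    (a noise draw clamped at zero), in which case X grows linearly."""
    if l * h > 1e-10:
        decay = math.exp(-l * h) if l * h < 50 else 0.0
        X *= decay
        X += (source / l) * (1.0 - decay)
    else:
        X += (source - l * X) * h


def _simulate_fixed(params, topology, transport, profile, grid, tau_end,
                    dt, save_every, noise_hooks, n_sub: int = 2):
    """Strang splitting: exact diffusion propagator around the reaction step.

    Diffusion is applied through the matrix exponential of the discrete
    ring Laplacian, so arbitrarily large diffusivities are unconditionally
    stable at a fixed step; the reaction part uses the L-stable
    exponential-Euler update above (``n_sub`` substeps per step).  Noise
    hooks are consulted once per step, so noise realizations are
    independent of any accuracy control.
    """
    N = grid.N
    ss = steady_state(params, topology, profile.I_L)
    A = np.full(N, ss.A)
    B = np.full(N, ss.B)
    C = np.full(N, ss.C)
    beta = transport.beta
    offs = grid.axial_offsets
    Lmat = _laplacian_matrix(grid)
    props = []
    for D in (transport.D_A, transport.D_B, transport.D_C):
        props.append(expm(0.5 * dt * D * Lmat) if D > 0 else None)

    n_steps = int(round(tau_end / dt))
    times, outA, outB, outC = [], [], [], []

    def store(k):
        times.append(k * dt)
        outA.append(A.copy())
        outB.append(B.copy())
        outC.append(C.copy())

    store(0)
    save_set = set(range(0, n_steps + 1, save_every))
    h = dt / n_sub
    for k in range(n_steps):
        tau = k * dt
        p = params if noise_hooks is None else noise_hooks.params_at(tau, params)
        for arr, P in ((A, props[0]), (B, props[1]), (C, props[2])):
            if P is not None:
                arr[:] = P @ arr
        for j in range(n_sub):
            t0 = tau + j * h
            x = beta * t0 + offs
            I = profile.field_at(x, beta)
            if noise_hooks is not None:
                I = noise_hooks.modify_input(t0, x, I)
            _reaction_step(A, B, C, I, h, p, topology)
        for arr, P in ((A, props[0]), (B, props[1]), (C, props[2])):
            if P is not None:
                arr[:] = P @ arr
        if (k + 1) in save_set:
            store(k + 1)

    return SpatialTrajectory(times=np.array(times), A=np.array(outA),
                             B=np.array(outB), C=np.array(outC), grid=grid,
                             baseline_C=np.full(N, ss.C))


def simulate_ring(params: CircuitParams, topology: Topology,
                  transport: DimensionlessTransport,
                  profile: GradientProfile, grid: RingGrid | None = None,
                  tau_end: float | None = None, *,
                  rtol: float = 1e-8, atol: float = 1e-11,
                  save_spacing: float = 0.05,
                  noise_hooks: NoiseHooks | None = None,
                  method: str | None = None,
                  dt: float = 0.01) -> SpatialTrajectory:
    """Simulate the ring cell traversing the gradient (method of lines).

    Starts from the spatially uniform steady state at I_L and runs to
    ``tau_end`` (default T_s + 20, long enough for re-adaptation at the
    plateau).  Deterministic runs use an adaptive stiff solver; runs with
    noise hooks use the fixed-step split-operator integrator so noise
    resampling is well defined.  ``method`` may force "adaptive" or "fixed".
    """
    grid = grid or RingGrid()
    if tau_end is None:
        tau_end = profile.T_s + 20.0
    if method is None:
        method = "fixed" if noise_hooks is not None else "adaptive"
    if method == "adaptive":
        if noise_hooks is not None:
            raise ValueError("noise hooks require the fixed-step integrator")
        n_out = int(round(tau_end / save_spacing))
        t_eval = np.linspace(0.0, tau_end, n_out + 1)
        return _simulate_adaptive(params, topology, transport, profile, grid,
                                  tau_end, rtol, atol, t_eval)
    if method == "fixed":
        save_every = max(1, int(round(save_spacing / dt)))
        return _simulate_fixed(params, topology, transport, profile, grid,
                               tau_end, dt, save_every, noise_hooks)
    raise ValueError(f"unknown method {method!r}")
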