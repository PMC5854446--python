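"""Stochastic forcing of the ring model and the ensemble viability criteria.

Two noise sources are modeled separately:

* **External** chemoattractant noise: the ligand field carries a frozen
  multiplicative random texture, piecewise constant over spatial patches of
  one cell diameter.  A moving cell therefore experiences slowly varying
  input fluctuations whose timescale is the patch crossing time 1/beta —
  low-frequency noise that can masquerade as a gradient.
* **Internal** kinetic noise: all seven rate constants are redrawn around
  their nominal values at a fixed resampling interval, giving fast,
  mean-reverting output fluctuations that largely average out over the run.

A strategy is *viable* for a parameter set when every stochastic replicate
yields strictly positive output for it; among viable strategies the one
with the larger mean output wins.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.stats import truncnorm

from .circuits import CircuitParams, Topology
from .ring import (
    DimensionlessTransport,
    GradientProfile,
    RingGrid,
    simulate_ring,
)
from .sensing import Decision, decide, spatial_output, temporal_output

__all__ = [
    "ExternalNoise",
    "InternalNoise",
    "EnsembleResult",
    "make_hooks",
    "perturb_params",
    "run_ensemble",
    "viability",
    "noise_decision",
]

_PERTURBED_RATES = ("k_IA", "k_IB", "k_CB", "k_AC", "l_FA", "l_FB", "l_BC")


@dataclass(frozen=True)
class ExternalNoise:
    """Frozen spatial texture on the ligand field.

    ``eta`` is the noise amplitude as a fraction of the gradient's total
    signal swing I_H - I_L, so eta = 1 means patch-to-patch fluctuations as
    large as the signal the cell is trying to read; ``patch_length`` is the
    spatial correlation length in cell diameters.  Patch deviates are
    zero-mean standard normals truncated at +-3 sigma; the noisy field is
    truncated below at zero concentration.
    """

    eta: float = 0.0
    patch_length: float = 1.0
    trunc_sigma: float = 3.0

    def __post_init__(self) -> None:
        if self.eta < 0 or self.patch_length <= 0:
            raise ValueError("require eta >= 0 and patch_length > 0")


@dataclass(frozen=True)
class InternalNoise:
    """Resampled kinetic-rate noise.

    ``nu`` is interpreted fractionally by default: each rate is redrawn as
    Normal(p0, nu * p0^2) — coefficient of variation sqrt(nu) — truncated
    at zero, every ``resample_interval`` time units.  ``fractional=False``
    switches to absolute variance nu.
    """

    nu: float = 0.0
    resample_interval: float = 0.1
    fractional: bool = True

    def __post_init__(self) -> None:
        if self.nu < 0 or self.resample_interval <= 0:
            raise ValueError("require nu >= 0 and resample_interval > 0")


def _unchecked_params(values: dict) -> CircuitParams:
    """Build CircuitParams bypassing positivity checks (noise may clamp a
    rate to exactly zero)."""
    p = object.__new__(CircuitParams)
    for k, v in values.items():
        object.__setattr__(p, k, float(v))
    return p


def perturb_params(params: CircuitParams, noise: InternalNoise,
                   rng: np.random.Generator) -> CircuitParams:
    """One random redraw of the seven kinetic rates (equilibrium constants
    are left untouched); negative draws are clamped to zero."""
    if noise.nu == 0.0:
        return params
    vals = params.to_dict()
    z = rng.standard_normal(len(_PERTURBED_RATES))
    for name, zi in zip(_PERTURBED_RATES, z):
        p0 = vals[name]
        sd = math.sqrt(noise.nu) * (p0 if noise.fractional else 1.0)
        vals[name] = max(0.0, p0 + sd * zi)
    return _unchecked_params(vals)


class _FrozenField:
    """Per-run realization of the external texture over the traversed range."""

    def __init__(self, noise: ExternalNoise, beta: float, tau_end: float,
                 seed) -> None:
        self.noise = noise
        L = noise.patch_length
        self.j_min = math.floor(-0.6 / L)
        j_max = math.floor((beta * tau_end + 0.6) / L)
        n = j_max - self.j_min + 1
        rng = np.random.default_rng(seed)
        s = noise.trunc_sigma
        self.values = truncnorm.rvs(-s, s, size=n, random_state=rng)

    def __call__(self, x: np.ndarray) -> np.ndarray:
        j = np.floor(x / self.noise.patch_length).astype(int) - self.j_min
        j = np.clip(j, 0, len(self.values) - 1)
        return self.values[j]


class _RunHooks:
    """Noise hooks bound to one replicate (one frozen field, one rate stream)."""

    def __init__(self, external: ExternalNoise | None,
                 internal: InternalNoise | None, beta: float, tau_end: float,
                 seed_field, seed_rates, input_scale: float = 0.0) -> None:
        self.field = (_FrozenField(external, beta, tau_end, seed_field)
                      if external is not None and external.eta > 0 else None)
        self.amplitude = (external.eta * input_scale
                          if external is not None else 0.0)
        self.internal = (internal
                         if internal is not None and internal.nu > 0 else None)
        self._rate_seed = seed_rates
        self._interval = -1
        self._params: CircuitParams | None = None

    def modify_input(self, tau: float, x: np.ndarray,
                     I_det: np.ndarray) -> np.ndarray:
        if self.field is None:
            return I_det
        return np.maximum(I_det + self.amplitude * self.field(x), 0.0)

    def params_at(self, tau: float, base: CircuitParams) -> CircuitParams:
        if self.internal is None:
            return base
        j = int(math.floor(tau / self.internal.resample_interval + 1e-9))
        if j != self._interval:
            rng = np.random.default_rng(
                np.random.SeedSequence(entropy=int(self._rate_seed),
                                       spawn_key=(j,)))
            self._params = perturb_params(base, self.internal, rng)
            self._interval = j
        return self._params


def make_hooks(external: ExternalNoise | None, internal: InternalNoise | None,
               beta: float, tau_end: float, seed: int, replicate: int = 0,
               input_scale: float = 0.0) -> _RunHooks:
    """Hooks for one replicate; (seed, replicate) fully determine the noise.

    ``input_scale`` is the gradient's signal swing I_H - I_L, the unit in
    which the external amplitude eta is expressed.
    """
    root = np.random.SeedSequence(entropy=seed, spawn_key=(replicate,))
    seed_field, seed_rates = (int(s) for s in root.generate_state(2))
    return _RunHooks(external, internal, beta, tau_end, seed_field, seed_rates,
                     input_scale)


@dataclass
class EnsembleResult:
    """Per-replicate sensing outputs plus the ensemble-level verdict."""

    O_T: np.ndarray
    O_S: np.ndarray
    decisions: list[Decision]
    viable_temporal: bool = field(init=False)
    viable_spatial: bool = field(init=False)
    decision: Decision = field(init=False)

    def __post_init__(self) -> None:
        self.viable_temporal = bool(np.all(self.O_T > 0.0))
        self.viable_spatial = bool(np.all(self.O_S > 0.0))
        self.decision = noise_decision(self)


def viability(ensemble: EnsembleResult, strategy: Decision) -> bool:
    """A strategy is viable iff every replicate's output for it is > 0."""
    if strategy is Decision.TEMPORAL:
        return bool(np.all(ensemble.O_T > 0.0))
    if strategy is Decision.SPATIAL:
        return bool(np.all(ensemble.O_S > 0.0))
    raise ValueError("viability is defined for temporal/spatial only")


def noise_decision(ensemble: EnsembleResult) -> Decision:
    """Failure when neither strategy is viable; otherwise the viable one, or
    — when both survive — the one with the larger mean output."""
    vt = bool(np.all(ensemble.O_T > 0.0))
    vs = bool(np.all(ensemble.O_S > 0.0))
    if not vt and not vs:
        return Decision.FAILURE
    if vt and not vs:
        return Decision.TEMPORAL
    if vs and not vt:
        return Decision.SPATIAL
    return decide(float(np.mean(ensemble.O_T)), float(np.mean(ensemble.O_S)))


def run_ensemble(params: CircuitParams, topology: Topology,
                 transport: DimensionlessTransport, profile: GradientProfile,
                 grid: RingGrid | None = None,
                 external: ExternalNoise | None = None,
                 internal: InternalNoise | None = None,
                 n_replicates: int = 10, base_seed: int = 0,
                 tau_end: float | None = None,
                 dt: float = 0.01) -> EnsembleResult:
    """n independent noisy ring runs (fixed-step integrator) for one set.

    Replicate seeds derive deterministically from ``base_seed``; a
    replicate whose integration fails scores (0, 0), which disqualifies
    both strategies from viability for this set.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    grid = grid or RingGrid()
    if tau_end is None:
        tau_end = profile.T_s + 20.0
    O_T = np.empty(n_replicates)
    O_S = np.empty(n_replicates)
    decisions = []
    scale = profile.I_H - profile.I_L
    for rep in range(n_replicates):
        hooks = make_hooks(external, internal, transport.beta, tau_end,
                           base_seed, rep, input_scale=scale)
        try:
            traj = simulate_ring(params, topology, transport, profile, grid,
                                 tau_end=tau_end, noise_hooks=hooks,
                                 method="fixed", dt=dt)
            O_T[rep] = temporal_output(traj)
            O_S[rep] = spatial_output(traj)
        except (RuntimeError, ValueError):
            O_T[rep] = 0.0
            O_S[rep] = 0.0
        decisions.append(decide(O_T[rep], O_S[rep]))
    return EnsembleResult(O_T=O_T, O_S=O_S, decisions=decisions)
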