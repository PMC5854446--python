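"""Random screen for parameter sets with high sensitivity and precision.

Rate constants are drawn log-uniformly over several orders of magnitude,
each set is scored on its step response with the sensitivity S and
adaptation precision P metrics, and the first sets clearing both thresholds
(in sampling order, so the screen is a pure filter) are kept for the
spatial simulations downstream.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import math

import numpy as np

from .circuits import (
    CircuitParams,
    NonAdaptiveParameters,
    StepStimulus,
    Topology,
    precision,
    sensitivity,
    simulate_point,
)

__all__ = [
    "ParamSampleSpec",
    "ScreenResult",
    "sample_parameter_sets",
    "evaluate_set",
    "select_passing",
    "screen",
    "save_results",
    "load_params",
]

#: rates span 4 orders of magnitude, equilibrium constants 4 below unity
DEFAULT_RATE_RANGE = (-1.0, 3.0)
DEFAULT_EQ_RANGE = (-3.0, 1.0)


@dataclass(frozen=True)
class ParamSampleSpec:
    """How to draw random circuit parameter sets (log10-uniform)."""

    n_samples: int
    topology: Topology
    rate_range: tuple[float, float] = DEFAULT_RATE_RANGE
    eq_const_range: tuple[float, float] = DEFAULT_EQ_RANGE
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 0:
            raise ValueError("n_samples must be >= 0")
        for lo, hi in (self.rate_range, self.eq_const_range):
            if not lo < hi:
                raise ValueError("ranges must satisfy lo < hi")


@dataclass(frozen=True)
class ScreenResult:
    params: CircuitParams
    S: float
    P: float
    ok: bool  # integration succeeded and metrics are defined

    def passed(self, s_min: float, p_min: float) -> bool:
        return self.ok and self.S >= s_min and self.P >= p_min


def sample_parameter_sets(spec: ParamSampleSpec) -> list[CircuitParams]:
    """Draw ``n_samples`` parameter sets; identical spec => identical list."""
    rng = np.random.default_rng(spec.seed)
    lo_r, hi_r = spec.rate_range
    lo_e, hi_e = spec.eq_const_range
    rates = 10.0 ** rng.uniform(lo_r, hi_r, size=(spec.n_samples, 6))
    eqs = 10.0 ** rng.uniform(lo_e, hi_e, size=(spec.n_samples, 2))
    out = []
    for (k_IA, k_IB, k_CB, k_AC, l_FA, l_FB), (K_AC, L_BC) in zip(rates, eqs):
        out.append(CircuitParams(k_IA=k_IA, k_IB=k_IB, k_CB=k_CB, k_AC=k_AC,
                                 l_FA=l_FA, l_FB=l_FB, K_AC=K_AC, L_BC=L_BC))
    return out


def evaluate_set(params: CircuitParams, topology: Topology,
                 stimulus: StepStimulus | None = None) -> ScreenResult:
    """Score one set on its step response; failures score (0, 0), never raise."""
    stimulus = stimulus or StepStimulus()
    try:
        traj = simulate_point(params, topology, stimulus, rtol=1e-8, atol=1e-11)
        S = sensitivity(traj, stimulus)
        P = precision(traj, stimulus)
    except (NonAdaptiveParameters, RuntimeError, ValueError):
        return ScreenResult(params, 0.0, 0.0, ok=False)
    return ScreenResult(params, S, P, ok=True)


def select_passing(results: Sequence[ScreenResult], s_min: float = 1.0,
                   p_min: float = 10.0, n_keep: int = 100
                   ) -> list[CircuitParams]:
    """First ``n_keep`` sets (sampling order) with S >= s_min and P >= p_min."""
    if s_min <= 0 or p_min <= 0:
        raise ValueError("thresholds must be > 0")
    if n_keep < 1:
        raise ValueError("n_keep must be >= 1")
    chosen = [r.params for r in results if r.passed(s_min, p_min)]
    if len(chosen) < n_keep:
        warnings.warn(
            f"only {len(chosen)} of the requested {n_keep} sets passed "
            f"(s_min={s_min}, p_min={p_min})", stacklevel=2)
    return chosen[:n_keep]


def screen(topology: Topology, n_samples: int = 10_000, seed: int = 0,
           s_min: float = 1.0, p_min: float = 10.0, n_keep: int = 100,
           stimulus: StepStimulus | None = None,
           ) -> tuple[list[CircuitParams], list[ScreenResult]]:
    """Sample, score and select in one pass, stopping once n_keep have passed.

    Returns (selected params, all results scored so far).  Scoring stops as
    soon as ``n_keep`` sets have passed, which keeps the screen cheap when
    the pass rate is high; the selected sets are identical to those of an
    exhaustive scan because selection is in sampling order.
    """
    spec = ParamSampleSpec(n_samples=n_samples, topology=topology, seed=seed)
    stimulus = stimulus or StepStimulus()
    results: list[ScreenResult] = []
    n_passed = 0
    for params in sample_parameter_sets(spec):
        r = evaluate_set(params, topology, stimulus)
        results.append(r)
        if r.passed(s_min, p_min):
            n_passed += 1
            if n_passed >= n_keep:
                break
    return select_passing(results, s_min, p_min, n_keep), results


def save_results(results: Iterable[ScreenResult], topology: Topology,
                 path) -> None:
    records = []
    for i, r in enumerate(results):
        rec = {"topology": topology.value, "seed_index": i, **r.params.to_dict(),
               "S": r.S, "P": "inf" if math.isinf(r.P) else r.P, "ok": r.ok}
        records.append(rec)
    with open(path, "w") as fh:
        json.dump(records, fh, indent=1)


def load_params(path) -> list[CircuitParams]:
    with open(path) as fh:
        records = json.load(fh)
    return [CircuitParams.from_dict(rec) for rec in records]
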