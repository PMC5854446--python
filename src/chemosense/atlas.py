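"""Classify real cells by the speed group beta and back-of-envelope physics.

The dimensionless group beta = v / (d * l_BC) — cell speed over the product
of cell diameter and signaling rate — separates temporal from spatial
sensors: beta > 1 favors temporal sensing, beta < 1 makes spatial sensing
feasible.  Because signaling rates are rarely measured, a cell is placed
relative to the band of decision boundaries spanned by plausible rates
(0.2–5 per second by default, anchored on the CheY dephosphorylation rate):
above the band it is called temporal for any plausible rate, below it a
spatial candidate — "candidate" because spatial sensing additionally needs
a slowly diffusing output protein and an activator diffusing more slowly
than its inactivator.

Two auxiliary estimators: the diffusive traversal time t = L^2 / D of a
protein across a cell, and the ratio of diffusion coefficients of two
proteins from their molecular weights (D inversely proportional to the
square root of the molecular weight).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from importlib import resources

import pandas as pd

__all__ = [
    "MotilityClass",
    "SensingClass",
    "CellRecord",
    "beta_value",
    "classify_cell",
    "traversal_time",
    "mw_diffusion_ratio",
    "classify_table",
    "demo_cells",
]


class MotilityClass(str, Enum):
    FLAGELLAR = "flagellar"
    CILIA = "cilia"
    LAMELLIPODIA_FILOPODIA = "lamellipodia_filopodia"
    PSEUDOPODIA = "pseudopodia"
    OTHER = "other"


class SensingClass(str, Enum):
    TEMPORAL = "temporal"
    SPATIAL_CANDIDATE = "spatial_candidate"
    BOUNDARY_BAND = "boundary_band"


@dataclass(frozen=True)
class CellRecord:
    """One cell/organism: name, diameter (um), speed (um/s), signaling rate
    (1/s; defaults to 1 when unknown), motility class."""

    name: str
    diameter_um: float
    speed_um_s: float
    l_bc_per_s: float = 1.0
    motility_class: MotilityClass = MotilityClass.OTHER

    def __post_init__(self) -> None:
        if self.diameter_um <= 0 or self.speed_um_s < 0 or self.l_bc_per_s <= 0:
            raise ValueError(
                "require diameter > 0, speed >= 0, signaling rate > 0")


def beta_value(v: float, d: float, l_BC: float = 1.0) -> float:
    """beta = v / (d * l_BC); v in um/s, d in um, l_BC in 1/s."""
    if d <= 0 or l_BC <= 0:
        raise ValueError("require d > 0 and l_BC > 0")
    if v < 0:
        raise ValueError("require v >= 0")
    return v / (d * l_BC)


def classify_cell(record: CellRecord, l_BC_low: float = 0.2,
                  l_BC_high: float = 5.0) -> SensingClass:
    """Place a cell relative to the beta = 1 decision band.

    beta > 1 for every signaling rate in [l_BC_low, l_BC_high] (i.e.
    v/d > l_BC_high) => temporal; beta < 1 throughout => spatial candidate;
    otherwise the cell sits inside the boundary band.
    """
    if not 0 < l_BC_low <= l_BC_high:
        raise ValueError("require 0 < l_BC_low <= l_BC_high")
    v_over_d = record.speed_um_s / record.diameter_um
    if v_over_d > l_BC_high:
        return SensingClass.TEMPORAL
    if v_over_d < l_BC_low:
        return SensingClass.SPATIAL_CANDIDATE
    return SensingClass.BOUNDARY_BAND


def traversal_time(L: float, D: float) -> float:
    """Diffusive traversal time t = L^2 / D (L in um, D in um^2/s)."""
    if D <= 0:
        raise ValueError("require D > 0")
    if L < 0:
        raise ValueError("require L >= 0")
    return L * L / D


def mw_diffusion_ratio(mw_num: float, mw_den: float) -> float:
    """Diffusion-rate ratio estimated from molecular weights.

    With D proportional to 1/sqrt(MW), returns sqrt(mw_num / mw_den): the
    factor by which the protein of weight ``mw_den`` out-diffuses the one
    of weight ``mw_num`` (weights in Da).
    """
    if mw_num <= 0 or mw_den <= 0:
        raise ValueError("molecular weights must be > 0")
    return math.sqrt(mw_num / mw_den)


def classify_table(cells: pd.DataFrame, l_BC_low: float = 0.2,
                   l_BC_high: float = 5.0) -> pd.DataFrame:
    """Add beta and sensing classification columns to a cell table.

    Expects columns name, diameter_um, speed_um_s and optionally
    l_bc_per_s (default 1) and motility_class.
    """
    out = cells.copy()
    if "l_bc_per_s" not in out:
        out["l_bc_per_s"] = 1.0
    out["l_bc_per_s"] = out["l_bc_per_s"].fillna(1.0)
    if "motility_class" not in out:
        out["motility_class"] = MotilityClass.OTHER.value
    records = [
        CellRecord(name=row["name"], diameter_um=row["diameter_um"],
                   speed_um_s=row["speed_um_s"], l_bc_per_s=row["l_bc_per_s"],
                   motility_class=MotilityClass(row["motility_class"]))
        for _, row in out.iterrows()
    ]
    out["beta"] = [beta_value(r.speed_um_s, r.diameter_um, r.l_bc_per_s)
                   for r in records]
    out["sensing_class"] = [classify_cell(r, l_BC_low, l_BC_high).value
                            for r in records]
    return out


def demo_cells() -> pd.DataFrame:
    """The bundled demo table (E. coli, with measured CheY kinetics)."""
    path = resources.files("chemosense").joinpath("data/demo_cells.csv")
    with resources.as_file(path) as p:
        return pd.read_csv(p)
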