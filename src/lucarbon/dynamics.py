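"""Closed-form carbon transition curves.

Aboveground carbon in regenerating forest follows a logistic curve from the
agricultural baseline towards the mature-forest equilibrium CAP. Soil
organic carbon (top 100 cm) decomposes linearly under agriculture — a fixed
fraction of the undisturbed stock is lost over a fixed horizon — and
recovers linearly at half that slope once agriculture stops. Root carbon
tracks aboveground carbon through a constant root:shoot ratio.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable

import pandas as pd

from .params import ForestTypeParams, GlobalConstants

__all__ = [
    "SoilState",
    "agb_regrowth",
    "equivalent_age",
    "soc_step",
    "degraded_agc",
    "pixel_stock",
    "curve_table",
]

# Inverse-curve round-trip tolerance, years.
AGE_TOL = 1e-6


@dataclass(frozen=True)
class SoilState:
    """Soil organic carbon state of one cohort.

    soc_ref is the undisturbed density from the soil map (tC/ha, top
    100 cm); soc_current the present density; years_under_agriculture the
    cumulative tilled years (saturates at the loss horizon).
    """

    soc_ref: float
    soc_current: float
    years_under_agriculture: int = 0

    def __post_init__(self) -> None:
        if self.soc_ref < 0:
            raise ValueError("soc_ref must be non-negative")
        if not -1e-9 <= self.soc_current <= self.soc_ref + 1e-9:
            raise ValueError("soc_current must lie in [0, soc_ref]")

    @property
    def recovery_deficit(self) -> float:
        return self.soc_ref - self.soc_current

    @classmethod
    def undisturbed(cls, soc_ref: float) -> "SoilState":
        return cls(soc_ref=soc_ref, soc_current=soc_ref)


def agb_regrowth(age: float, params: ForestTypeParams) -> float:
    """Aboveground carbon (tC/ha) of regrowth of the given age.

    Logistic: CAP / (1 + exp(alpha - beta * age)). Strictly increasing in
    age, asymptote CAP; by calibration the value at age 0 is the
    agricultural baseline and at t99 it is 99% of CAP.
    """
    if age < 0:
        raise ValueError("regrowth age must be non-negative")
    return params.cap_agc / (1.0 + math.exp(params.alpha - params.beta * age))


def equivalent_age(agc: float, params: ForestTypeParams) -> float:
    """Invert the regrowth curve: the age whose carbon equals ``agc``.

    Clamped: carbon at or below the age-0 value maps to 0; carbon at or
    above 99% of CAP maps to t99.
    """
    floor = agb_regrowth(0.0, params)
    if agc <= floor:
        return 0.0
    if agc >= 0.99 * params.cap_agc:
        return params.t99
    return (params.alpha - math.log(params.cap_agc / agc - 1.0)) / params.beta


def soc_step(
    state: SoilState, land_class: str, constants: GlobalConstants
) -> SoilState:
    """Advance a soil state by one year.

    ``land_class`` is one of ``agriculture`` (linear decomposition towards
    the (1 - soc_loss_frac) floor, stopping once the cumulative tilled
    years reach the horizon), ``recovering`` (linear recovery towards
    soc_ref at recovery_slope_factor times the decomposition slope) or
    ``undisturbed`` (no change).
    """
    slope = constants.soc_loss_frac * state.soc_ref / constants.soc_loss_horizon
    if land_class == "agriculture":
        if state.years_under_agriculture >= constants.soc_loss_horizon:
            return replace(
                state, years_under_agriculture=constants.soc_loss_horizon
            )
        floor = (1.0 - constants.soc_loss_frac) * state.soc_ref
        return SoilState(
            soc_ref=state.soc_ref,
            soc_current=max(floor, state.soc_current - slope),
            years_under_agriculture=state.years_under_agriculture + 1,
        )
    if land_class == "recovering":
        if state.recovery_deficit <= 0:
            return state
        gain = constants.recovery_slope_factor * slope
        return replace(
            state, soc_current=min(state.soc_ref, state.soc_current + gain)
        )
    if land_class == "undisturbed":
        return state
    raise ValueError(f"unknown soil land class {land_class!r}")


def degraded_agc(params: ForestTypeParams, equiv_age: float | None = None) -> float:
    """Aboveground carbon assigned to degraded forest.

    Degraded forest (partially logged/burned, never fully cleared) is given
    the carbon of fixed-age regrowth — 25 years by default, 15 in the
    severe-degradation scenario. Soil carbon is left intact by the caller.
    """
    age = params.degraded_equiv_age if equiv_age is None else equiv_age
    if age <= 0:
        raise ValueError("degraded equivalent age must be positive")
    return agb_regrowth(age, params)


def pixel_stock(
    agc: float, soil: SoilState, params: ForestTypeParams | None
) -> float:
    """Total carbon density (tC/ha): shoots + roots + soil.

    Root carbon is agc * root_shoot; with no forest type (never-forested
    land) root carbon is zero.
    """
    if agc < 0:
        raise ValueError("aboveground carbon must be non-negative")
    root_shoot = params.root_shoot if params is not None else 0.0
    return agc * (1.0 + root_shoot) + soil.soc_current


def curve_table(
    forest_types: Iterable[ForestTypeParams], max_age: int = 50
) -> pd.DataFrame:
    """Regrowth curves as a tidy table (age, forest_type, agc_tc_ha)."""
    rows = [
        {"age": a, "forest_type": p.name, "agc_tc_ha": agb_regrowth(a, p)}
        for p in forest_types
        for a in range(max_age + 1)
    ]
    return pd.DataFrame(rows)
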