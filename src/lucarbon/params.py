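"""Equilibrium carbon parameters for the bookkeeping model.

Mature-forest aboveground carbon (CAP) is estimated per forest type from
the biomass distribution of nearly intact reference pixels; the logistic
regrowth curve for each type is then calibrated from two boundary
conditions: carbon equals the agricultural baseline (5 tC/ha) at age 0 and
reaches 99% of CAP at the type's recovery horizon (40 years for humid
forest, 35 for dry/seasonal forest).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GlobalConstants",
    "ForestTypeParams",
    "ParamSet",
    "DEFAULT_FOREST_TYPES",
    "estimate_cap",
    "calibrate_logistic",
    "build_params",
]


@dataclass(frozen=True)
class GlobalConstants:
    """Scalar constants shared across forest types.

    Attributes
    ----------
    agri_agc : aboveground carbon of cropland/pasture, tC/ha.
    carbon_fraction : carbon content per unit living biomass.
    co2_per_c : mass conversion from carbon to CO2 (44/12).
    soc_loss_frac : fraction of soil organic carbon lost under agriculture.
    soc_loss_horizon : years over which that loss accrues linearly.
    recovery_slope_factor : SOC recovery slope relative to the
        decomposition slope (0.5 = recovery takes twice as long).
    other_veg_agc : aboveground carbon assigned to non-forest vegetation.
    """

    agri_agc: float = 5.0
    carbon_fraction: float = 0.5
    co2_per_c: float = 44.0 / 12.0
    soc_loss_frac: float = 0.25
    soc_loss_horizon: int = 20
    recovery_slope_factor: float = 0.5
    other_veg_agc: float = 5.0

    def __post_init__(self) -> None:
        for name in (
            "agri_agc",
            "carbon_fraction",
            "co2_per_c",
            "soc_loss_horizon",
            "recovery_slope_factor",
            "other_veg_agc",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if not 0.0 < self.soc_loss_frac < 1.0:
            raise ValueError("soc_loss_frac must lie in (0, 1)")


@dataclass(frozen=True)
class ForestTypeParams:
    """Per-forest-type equilibrium carbon and regrowth-curve parameters."""

    name: str
    cap_agc: float  # mature aboveground carbon, tC/ha
    t99: float  # years to reach 99% of cap_agc
    alpha: float  # logistic offset, dimensionless
    beta: float  # logistic rate, 1/year
    root_shoot: float  # belowground:aboveground biomass ratio
    degraded_equiv_age: float = 25.0  # regrowth age assigned to degraded forest

    def __post_init__(self) -> None:
        if self.beta <= 0:
            raise ValueError(f"{self.name}: beta must be positive")
        if self.root_shoot < 0:
            raise ValueError(f"{self.name}: root_shoot must be non-negative")


@dataclass(frozen=True)
class ParamSet:
    """Complete parameterisation: one ForestTypeParams per type + constants."""

    forest_types: Mapping[str, ForestTypeParams]
    constants: GlobalConstants = field(default_factory=GlobalConstants)

    def __getitem__(self, name: str) -> ForestTypeParams:
        try:
            return self.forest_types[name]
        except KeyError:
            raise KeyError(
                f"unknown forest type {name!r}; valid names: "
                f"{sorted(self.forest_types)}"
            ) from None


# The nine national forest types. `humid` selects the 40-year recovery
# horizon (vs 35 for dry/seasonal types) and the default root:shoot ratio
# (0.24 moist, 0.28 dry; IPCC-style defaults, overridable in config).
DEFAULT_FOREST_TYPES: dict[str, dict] = {
    "amazon": {"humid": True},
    "chaco": {"humid": False},
    "chiquitano": {"humid": False},
    "yungas": {"humid": True},
    "flooded_beni": {"humid": True},
    "pantanal": {"humid": True},
    "tucumano": {"humid": True},
    "dry_inter_andean": {"humid": False},
    "andean": {"humid": False},
}

_T99_HUMID = 40.0
_T99_DRY = 35.0
_ROOT_SHOOT_HUMID = 0.24
_ROOT_SHOOT_DRY = 0.28


def estimate_cap(
    biomass_samples: Sequence[float],
    percentile: float,
    carbon_fraction: float = 0.5,
    forest_type: str | None = None,
) -> float:
    """Mature aboveground carbon (tC/ha) from intact-pixel biomass samples.

    Takes the requested percentile of the aboveground biomass distribution
    (linear interpolation between closest ranks) and converts biomass to
    carbon with ``carbon_fraction``.
    """
    samples = np.asarray(biomass_samples, dtype=float)
    if samples.size == 0:
        label = f" for forest type {forest_type!r}" if forest_type else ""
        raise ValueError(f"no intact biomass samples{label}")
    if np.any(samples < 0):
        raise ValueError("biomass samples must be non-negative")
    if not 0.0 < percentile < 100.0:
        raise ValueError("percentile must lie in (0, 100)")
    return float(carbon_fraction * np.percentile(samples, percentile))


def calibrate_logistic(
    cap_agc: float,
    initial_agc: float = 5.0,
    target_frac: float = 0.99,
    t99: float = 40.0,
) -> tuple[float, float]:
    """Solve the logistic curve CAP/(1+exp(alpha - beta*a)) for (alpha, beta).

    Boundary conditions: the curve equals ``initial_agc`` at age 0 and
    ``target_frac * cap_agc`` at age ``t99``. Closed form:

        alpha = ln(cap/initial - 1)
        beta  = (alpha - ln(1/target_frac - 1)) / t99
    """
    if cap_agc <= initial_agc:
        raise ValueError(
            f"cannot calibrate: cap_agc={cap_agc} must exceed "
            f"initial_agc={initial_agc} (curve starts above its asymptote)"
        )
    if initial_agc <= 0:
        raise ValueError("initial_agc must be positive")
    if not 0.0 < target_frac < 1.0:
        raise ValueError("target_frac must lie in (0, 1)")
    if t99 <= 0:
        raise ValueError("t99 must be positive")
    alpha = math.log(cap_agc / initial_agc - 1.0)
    beta = (alpha - math.log(1.0 / target_frac - 1.0)) / t99
    return alpha, beta


def build_params(
    config: Mapping | None = None,
    biomass_table: pd.DataFrame | None = None,
) -> ParamSet:
    """Assemble a full ParamSet from a config mapping and intact-biomass table.

    ``config`` may carry blocks ``constants`` (GlobalConstants overrides),
    ``percentile`` (CAP percentile, default 50), ``degraded_equiv_age`` and
    ``forest_types`` (per-type overrides: ``cap_agc``, ``t99``,
    ``root_shoot``, ``alpha``/``beta`` to drop in published curve
    parameters). ``biomass_table`` needs columns ``forest_type``,
    ``biomass_t_ha`` and optionally ``intact_flag`` (non-intact rows are
    excluded from the CAP percentile).
    """
    config = dict(config or {})
    constants = GlobalConstants(**config.get("constants", {}))
    percentile = float(config.get("percentile", 50.0))
    degraded_age = float(config.get("degraded_equiv_age", 25.0))
    type_cfg: Mapping[str, Mapping] = config.get("forest_types", {})

    names = list(type_cfg) if type_cfg else list(DEFAULT_FOREST_TYPES)
    for name in names:
        if name not in DEFAULT_FOREST_TYPES and "t99" not in type_cfg.get(name, {}):
            raise ValueError(
                f"unknown forest type {name!r}; valid names: "
                f"{sorted(DEFAULT_FOREST_TYPES)} (or supply t99 explicitly)"
            )

    samples_by_type: dict[str, np.ndarray] = {}
    if biomass_table is not None:
        table = biomass_table
        if "intact_flag" in table.columns:
            table = table[table["intact_flag"].astype(bool)]
        for name, grp in table.groupby("forest_type"):
            samples_by_type[str(name)] = grp["biomass_t_ha"].to_numpy(float)

    forest_types: dict[str, ForestTypeParams] = {}
    for name in names:
        cfg = dict(type_cfg.get(name, {}))
        humid = DEFAULT_FOREST_TYPES.get(name, {}).get("humid", True)
        t99 = float(cfg.get("t99", _T99_HUMID if humid else _T99_DRY))
        root_shoot = float(
            cfg.get("root_shoot", _ROOT_SHOOT_HUMID if humid else _ROOT_SHOOT_DRY)
        )
        if "cap_agc" in cfg:
            cap = float(cfg["cap_agc"])
        elif name in samples_by_type:
            cap = estimate_cap(
                samples_by_type[name],
                percentile,
                constants.carbon_fraction,
                forest_type=name,
            )
        else:
            raise ValueError(
                f"forest type {name!r} has neither intact biomass samples "
                "nor an explicit cap_agc override"
            )
        if "alpha" in cfg and "beta" in cfg:
            alpha, beta = float(cfg["alpha"]), float(cfg["beta"])
        else:
            alpha, beta = calibrate_logistic(
                cap, constants.agri_agc, 0.99, t99
            )
        forest_types[name] = ForestTypeParams(
            name=name,
            cap_agc=cap,
            t99=t99,
            alpha=alpha,
            beta=beta,
            root_shoot=root_shoot,
            degraded_equiv_age=float(cfg.get("degraded_equiv_age", degraded_age)),
        )
    return ParamSet(forest_types=forest_types, constants=constants)


def with_degraded_age(params: ParamSet, age: float) -> ParamSet:
    """Return a copy of ``params`` with every type's degraded age replaced."""
    return ParamSet(
        forest_types={
            k: replace(v, degraded_equiv_age=age)
            for k, v in params.forest_types.items()
        },
        constants=params.constants,
    )
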