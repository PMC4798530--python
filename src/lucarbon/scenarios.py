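"""Sensitivity scenarios, static-land adjustments and the Tier 1 comparator.

Five deviations from the baseline bookkeeping assumptions are modelled:
clearing less dense forest first (25th instead of 50th biomass percentile
for mature carbon), a 20% pasture share with intact soil carbon, more
aggressive agriculture (35% instead of 25% soil carbon loss), severe forest
degradation (degraded carbon of 15- instead of 25-year regrowth), plus two
adjustments on lands whose cover never changed: soil-erosion emissions from
static non-forested land and a growth sink in mature forests. A Tier 1
committed-emissions calculation (average forest loss times average carbon
density) serves as the naive comparator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from . import reporting
from .bookkeeping import GridResult, InitConfig, run_grid
from .params import ParamSet, build_params

__all__ = [
    "ErosionSpec",
    "MatureSinkSpec",
    "ScenarioSpec",
    "SCENARIOS",
    "apply_scenario",
    "erosion_flux",
    "mature_sink_flux",
    "tier1",
    "forest_area",
    "run_scenario",
    "run_all",
]

_BASELINE = dict(
    cap_percentile=50.0, pasture_share=0.0, soc_loss_frac=0.25,
    degraded_equiv_age=25.0,
)


@dataclass(frozen=True)
class ErosionSpec:
    """Soil-erosion flux from static non-forested land."""

    eroding_share: float = 0.80  # share of non-forested area losing soil
    annual_soc_loss: float = 0.01  # fraction of SOC stock eroded per year
    oxidized_frac: float = 0.015  # fraction of eroded carbon emitted as CO2
    depleting_stock: bool = True  # deplete the stock year-on-year

    def __post_init__(self) -> None:
        for name in ("eroding_share", "annual_soc_loss", "oxidized_frac"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")


@dataclass(frozen=True)
class MatureSinkSpec:
    """Biomass growth in mature (static) forests."""

    growth_per_decade: float = 0.04

    def __post_init__(self) -> None:
        if not 0.0 <= self.growth_per_decade <= 1.0:
            raise ValueError("growth_per_decade must lie in [0, 1]")


@dataclass(frozen=True)
class ScenarioSpec:
    """A named deviation set from the baseline assumptions."""

    name: str
    cap_percentile: float = 50.0
    pasture_share: float = 0.0
    soc_loss_frac: float = 0.25
    degraded_equiv_age: float = 25.0
    erosion: ErosionSpec | None = None
    mature_sink: MatureSinkSpec | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.cap_percentile < 100.0:
            raise ValueError("cap_percentile must lie in (0, 100)")
        if not 0.0 <= self.pasture_share <= 1.0:
            raise ValueError("pasture_share must lie in [0, 1]")
        if not 0.0 < self.soc_loss_frac < 1.0:
            raise ValueError("soc_loss_frac must lie in (0, 1)")
        if self.degraded_equiv_age <= 0:
            raise ValueError("degraded_equiv_age must be positive")
        if self.name == "baseline":
            for key, val in _BASELINE.items():
                if getattr(self, key) != val:
                    raise ValueError(
                        f"baseline scenario must keep {key}={val}"
                    )
            if self.erosion is not None or self.mature_sink is not None:
                raise ValueError("baseline scenario has no static-land options")


SCENARIOS: dict[str, ScenarioSpec] = {
    s.name: s
    for s in (
        ScenarioSpec("baseline"),
        ScenarioSpec("clearing_less_dense_first", cap_percentile=25.0),
        ScenarioSpec("pasture_20pct", pasture_share=0.20),
        ScenarioSpec("aggressive_agriculture", soc_loss_frac=0.35),
        ScenarioSpec("severe_degradation", degraded_equiv_age=15.0),
        ScenarioSpec("erosion", erosion=ErosionSpec()),
        ScenarioSpec("mature_forest_sink", mature_sink=MatureSinkSpec()),
    )
}


def apply_scenario(base_config: Mapping | None, spec: ScenarioSpec) -> dict:
    """Merge a scenario's knobs into a parameter-building config (pure)."""
    config = {k: v for k, v in dict(base_config or {}).items()}
    config["percentile"] = spec.cap_percentile
    config["degraded_equiv_age"] = spec.degraded_equiv_age
    constants = dict(config.get("constants", {}))
    constants["soc_loss_frac"] = spec.soc_loss_frac
    config["constants"] = constants
    return config


def _start_cover_column(period: str) -> str:
    return {"1990-2000": "cover_1990", "2000-2010": "cover_2000"}[period]


def _end_cover_column(period: str) -> str:
    return {"1990-2000": "cover_2000", "2000-2010": "cover_2010"}[period]


def erosion_flux(
    grid: pd.DataFrame,
    params: ParamSet,
    spec: ErosionSpec,
    decade_years: int = 10,
    periods: Sequence[str] = ("1990-2000", "2000-2010"),
) -> pd.DataFrame:
    """Annual CO2 flux (tCO2) from soil erosion on static non-forested land.

    For the eroding share of each pixel observed as non-forested at the
    decade's start, ``annual_soc_loss`` of the SOC stock erodes each year
    and ``oxidized_frac`` of the eroded carbon is emitted; the remainder is
    redeposited off-ledger. The stock either depletes year-on-year or is
    held constant.
    """
    co2 = params.constants.co2_per_c
    rows = []
    for period in periods:
        start_col = _start_cover_column(period)
        nonforest = grid[~grid[start_col].isin(("forest", "regrowth"))]
        for rec in nonforest.itertuples():
            stock = rec.soc_ref * rec.area_ha * spec.eroding_share  # tC
            for year in range(1, decade_years + 1):
                eroded = spec.annual_soc_loss * stock
                rows.append(
                    {
                        "pixel_id": rec.pixel_id,
                        "period": period,
                        "year": year,
                        "flux_tco2": spec.oxidized_frac * eroded * co2,
                    }
                )
                if spec.depleting_stock:
                    stock -= eroded
    return pd.DataFrame(
        rows, columns=["pixel_id", "period", "year", "flux_tco2"]
    )


def mature_sink_flux(
    grid: pd.DataFrame,
    params: ParamSet,
    spec: MatureSinkSpec,
    decade_years: int = 10,
    periods: Sequence[str] = ("1990-2000", "2000-2010"),
) -> pd.DataFrame:
    """Annual CO2 absorption (negative tCO2) by static mature forests.

    Pixels observed as forest at both ends of a decade gain
    growth_per_decade * CAP * (1 + root_shoot) carbon per hectare per
    decade, spread linearly over its years.
    """
    co2 = params.constants.co2_per_c
    rows = []
    for period in periods:
        start_col = _start_cover_column(period)
        end_col = _end_cover_column(period)
        mature = grid[
            (grid[start_col] == "forest") & (grid[end_col] == "forest")
        ]
        for rec in mature.itertuples():
            ftp = params[rec.forest_type]
            annual_gain = (
                spec.growth_per_decade
                * ftp.cap_agc
                * (1.0 + ftp.root_shoot)
                / decade_years
            )
            flux = -annual_gain * rec.area_ha * co2
            for year in range(1, decade_years + 1):
                rows.append(
                    {
                        "pixel_id": rec.pixel_id,
                        "period": period,
                        "year": year,
                        "flux_tco2": flux,
                    }
                )
    return pd.DataFrame(
        rows, columns=["pixel_id", "period", "year", "flux_tco2"]
    )


def tier1(
    forest_area_start: float,
    forest_area_end: float,
    mean_agc: float,
    years: int,
    co2_per_c: float = 44.0 / 12.0,
) -> float:
    """Tier 1 committed emissions: average annual forest loss (ha/yr) times
    average aboveground carbon density (tC/ha) times 44/12, in tCO2/yr."""
    if years <= 0:
        raise ValueError("years must be positive")
    return (forest_area_start - forest_area_end) / years * mean_agc * co2_per_c


def forest_area(grid: pd.DataFrame, epoch_column: str) -> float:
    """Total area (ha) of mature forest at one epoch, excluding degraded
    and regenerating forest."""
    return float(grid.loc[grid[epoch_column] == "forest", "area_ha"].sum())


@dataclass(frozen=True)
class ScenarioResult:
    spec: ScenarioSpec
    grid_result: GridResult
    adjustments: pd.DataFrame  # per period: erosion/sink totals, tCO2
    national: pd.DataFrame = field(init=False)  # adjusted per-period totals

    def __post_init__(self) -> None:
        national = self.grid_result.national.copy()
        if len(self.adjustments):
            adj = self.adjustments.groupby("period")["flux_tco2"].sum()
            national["total_tco2"] = national["total_tco2"] + national[
                "period"
            ].map(adj).fillna(0.0)
            years = (
                int(self.grid_result.annual["year"].max())
                if len(self.grid_result.annual)
                else 10
            )
            national["avg_annual_tco2"] = national["total_tco2"] / years
        object.__setattr__(self, "national", national)


def run_scenario(
    grid: pd.DataFrame,
    biomass_table: pd.DataFrame,
    spec: ScenarioSpec,
    base_config: Mapping | None = None,
    init: InitConfig | None = None,
    decade_years: int = 10,
) -> ScenarioResult:
    """Run the full engine under one scenario, including static-land fluxes."""
    params = build_params(apply_scenario(base_config, spec), biomass_table)
    grid_result = run_grid(grid, params, spec, init, decade_years)
    pieces = []
    if spec.erosion is not None:
        pieces.append(erosion_flux(grid, params, spec.erosion, decade_years))
    if spec.mature_sink is not None:
        pieces.append(
            mature_sink_flux(grid, params, spec.mature_sink, decade_years)
        )
    adjustments = (
        pd.concat(pieces, ignore_index=True)
        if pieces
        else pd.DataFrame(columns=["pixel_id", "period", "year", "flux_tco2"])
    )
    return ScenarioResult(spec=spec, grid_result=grid_result, adjustments=adjustments)


def run_all(
    grid: pd.DataFrame,
    biomass_table: pd.DataFrame,
    admin: pd.DataFrame | None = None,
    base_config: Mapping | None = None,
    specs: Mapping[str, ScenarioSpec] | None = None,
    init: InitConfig | None = None,
) -> pd.DataFrame:
    """Sensitivity table: one row per scenario x period with average annual
    net emissions and (if admin stats are given) per-capita emissions."""
    specs = specs or SCENARIOS
    rows = []
    for spec in specs.values():
        result = run_scenario(grid, biomass_table, spec, base_config, init)
        for rec in result.national.itertuples():
            row = {
                "scenario": spec.name,
                "period": rec.period,
                "avg_annual_tco2": rec.avg_annual_tco2,
            }
            if admin is not None:
                pop = reporting.national_population(admin, rec.period)
                row["per_capita_tco2"] = reporting.per_capita(
                    rec.avg_annual_tco2, pop
                )
            rows.append(row)
    return pd.DataFrame(rows)
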