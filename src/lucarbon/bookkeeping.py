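"""Tier 3 cohort bookkeeping engine.

Each ~10x10 km pixel carries an observed land-cover class at three epochs
(1990, 2000, 2010). The engine expands each decadal transition into annual
conversion events — by default one tenth of the transitioning area converts
in each year of the decade, since the within-decade timing is unobserved —
and steps sub-pixel cohorts through the carbon transition curves year by
year. Net flux is pure mass balance: the change in total carbon stock
(shoots + roots + soil) times 44/12, positive for emission.

Cohort classes extend the observed vocabulary with two internal states:
``degraded`` (forest observed as regrowth without prior clearing) and
``pasture`` (cleared land whose soil carbon stays intact, used by the
pasture-share scenario).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .dynamics import (
    SoilState,
    agb_regrowth,
    degraded_agc,
    equivalent_age,
    pixel_stock,
    soc_step,
)
from .params import ForestTypeParams, GlobalConstants, ParamSet

__all__ = [
    "COVER_CLASSES",
    "PixelRecord",
    "Cohort",
    "ConversionEvent",
    "EmissionsResult",
    "GridResult",
    "InitConfig",
    "init_state",
    "expand_transition",
    "step_year",
    "run_pixel",
    "run_grid",
    "validate_grid",
]

# Observed land-cover vocabulary (satellite classes).
COVER_CLASSES = (
    "forest",
    "regrowth",
    "agriculture",
    "other_vegetation",
    "nonvegetated",
)
# Internal cohort classes.
COHORT_CLASSES = COVER_CLASSES + ("degraded", "pasture")
FORESTED_CLASSES = ("forest", "regrowth")

EPOCH_COLUMNS = ("cover_1990", "cover_2000", "cover_2010")
PERIODS = ("1990-2000", "2000-2010")

_AREA_TOL = 1e-9
_FRAC_EPS = 1e-15

# Soil dynamics mode by cohort class: tilled land decomposes, vegetated
# land recovers any deficit, bare land and (by assumption) pasture are
# static.
_SOIL_MODE = {
    "agriculture": "agriculture",
    "pasture": "undisturbed",
    "forest": "recovering",
    "regrowth": "recovering",
    "degraded": "recovering",
    "other_vegetation": "recovering",
    "nonvegetated": "undisturbed",
}


@dataclass(frozen=True)
class PixelRecord:
    """One grid cell of the national 10x10 km lattice."""

    pixel_id: str
    area_ha: float
    forest_type: str | None
    agb_biomass_t_ha: float
    soc_ref: float
    department: str
    municipality: str
    cover_1990: str
    cover_2000: str
    cover_2010: str

    def __post_init__(self) -> None:
        if self.area_ha <= 0:
            raise ValueError(f"pixel {self.pixel_id}: area_ha must be positive")
        for col in EPOCH_COLUMNS:
            cover = getattr(self, col)
            if cover not in COVER_CLASSES:
                raise ValueError(
                    f"pixel {self.pixel_id}: unknown cover class {cover!r} "
                    f"in {col}; valid classes: {COVER_CLASSES}"
                )
        if self.ever_forested and self.forest_type is None:
            raise ValueError(
                f"pixel {self.pixel_id}: forest_type required when any "
                "epoch class is forest or regrowth"
            )

    @property
    def ever_forested(self) -> bool:
        return any(getattr(self, c) in FORESTED_CLASSES for c in EPOCH_COLUMNS)

    @classmethod
    def from_row(cls, row: Mapping) -> "PixelRecord":
        ft = row.get("forest_type")
        if ft is None or (isinstance(ft, float) and np.isnan(ft)) or ft == "":
            ft = None
        return cls(
            pixel_id=str(row["pixel_id"]),
            area_ha=float(row["area_ha"]),
            forest_type=ft,
            agb_biomass_t_ha=float(row.get("agb_biomass_t_ha", 0.0) or 0.0),
            soc_ref=float(row["soc_ref"]),
            department=str(row["department"]),
            municipality=str(row["municipality"]),
            cover_1990=str(row["cover_1990"]),
            cover_2000=str(row["cover_2000"]),
            cover_2010=str(row["cover_2010"]),
        )


@dataclass
class Cohort:
    """A sub-pixel area fraction sharing class, age and soil history."""

    land_class: str
    area_fraction: float
    age: float  # regrowth age, years (meaningful for regrowth/degraded)
    agc: float  # aboveground carbon, tC/ha
    soil: SoilState
    ever_cleared: bool = False


@dataclass(frozen=True)
class ConversionEvent:
    """Convert ``area_fraction`` of ``cohort`` towards an observed class."""

    cohort: Cohort
    area_fraction: float
    target: str


@dataclass(frozen=True)
class EmissionsResult:
    """Net CO2 flux of one pixel over one decade (tCO2; emission positive)."""

    pixel_id: str
    period: str
    annual_net_flux: np.ndarray
    period_total: float
    stock_start_tc: float
    stock_end_tc: float


@dataclass(frozen=True)
class InitConfig:
    """1990 initial-state assumptions (fallow age structure unobserved).

    Regrowth pixels start as equal-weight cohorts at integer ages
    ``regrowth_age_min..regrowth_age_max``; agricultural pixels are assumed
    to have been tilled for ``prior_agri_years`` already. With
    ``forest_at_observed_carbon`` mature forest starts at the pixel's
    mapped carbon instead of the type CAP.
    """

    regrowth_age_min: int = 1
    regrowth_age_max: int = 10
    prior_agri_years: int = 10
    forest_at_observed_carbon: bool = False


def _soil_after_agriculture(
    soc_ref: float, years: int, constants: GlobalConstants
) -> SoilState:
    state = SoilState.undisturbed(soc_ref)
    for _ in range(years):
        state = soc_step(state, "agriculture", constants)
    return state


def init_state(
    pixel: PixelRecord,
    params: ParamSet,
    init: InitConfig | None = None,
) -> list[Cohort]:
    """Seed the 1990 cohort set from the first observed cover class."""
    init = init or InitConfig()
    constants = params.constants
    cover = pixel.cover_1990
    ftp = params[pixel.forest_type] if pixel.forest_type is not None else None
    soc = pixel.soc_ref

    if cover == "forest":
        if ftp is None:
            raise ValueError(
                f"pixel {pixel.pixel_id}: forest cover without forest_type"
            )
        agc = ftp.cap_agc
        if init.forest_at_observed_carbon and pixel.agb_biomass_t_ha > 0:
            agc = min(
                ftp.cap_agc, constants.carbon_fraction * pixel.agb_biomass_t_ha
            )
        return [Cohort("forest", 1.0, 0.0, agc, SoilState.undisturbed(soc))]

    if cover == "regrowth":
        if ftp is None:
            raise ValueError(
                f"pixel {pixel.pixel_id}: regrowth cover without forest_type"
            )
        ages = range(init.regrowth_age_min, init.regrowth_age_max + 1)
        frac = 1.0 / len(list(ages))
        cohorts = []
        for age in range(init.regrowth_age_min, init.regrowth_age_max + 1):
            soil = _soil_after_agriculture(soc, init.prior_agri_years, constants)
            for _ in range(age):
                soil = soc_step(soil, "recovering", constants)
            cohorts.append(
                Cohort(
                    "regrowth",
                    frac,
                    float(age),
                    agb_regrowth(float(age), ftp),
                    soil,
                    ever_cleared=True,
                )
            )
        return cohorts

    if cover == "agriculture":
        soil = _soil_after_agriculture(soc, init.prior_agri_years, constants)
        return [
            Cohort(
                "agriculture", 1.0, 0.0, constants.agri_agc, soil,
                ever_cleared=True,
            )
        ]

    if cover == "other_vegetation":
        return [
            Cohort(
                "other_vegetation", 1.0, 0.0, constants.other_veg_agc,
                SoilState.undisturbed(soc),
            )
        ]

    if cover == "nonvegetated":
        return [Cohort("nonvegetated", 1.0, 0.0, 0.0, SoilState.undisturbed(soc))]

    raise ValueError(f"unknown cover class {cover!r}")


def expand_transition(
    cover_start: str,
    cover_end: str,
    decade_years: int = 10,
    cohort_rule: str = "uniform",
) -> list[tuple[int, float]]:
    """Schedule of (year, fraction-of-source) conversion events for a decade.

    ``uniform`` converts 1/decade_years of the transitioning area in each
    year; ``midpoint`` converts everything at mid-decade. Identity
    transitions produce no events (cohorts still age and recover).
    """
    for cover in (cover_start, cover_end):
        if cover not in COVER_CLASSES:
            raise ValueError(
                f"unknown cover class {cover!r}; valid classes: {COVER_CLASSES}"
            )
    if cover_start == cover_end:
        return []
    if cohort_rule == "uniform":
        return [(year, 1.0 / decade_years) for year in range(1, decade_years + 1)]
    if cohort_rule == "midpoint":
        return [((decade_years + 1) // 2, 1.0)]
    raise ValueError(f"unknown cohort rule {cohort_rule!r}")


def _evolve(cohort: Cohort, ftp: ForestTypeParams | None, constants: GlobalConstants) -> None:
    """Age a cohort by one year along its class's transition curve."""
    if cohort.land_class == "regrowth":
        cohort.age += 1.0
        cohort.agc = agb_regrowth(cohort.age, ftp)
    cohort.soil = soc_step(cohort.soil, _SOIL_MODE[cohort.land_class], constants)


def _converted(
    source: Cohort,
    frac: float,
    target: str,
    ftp: ForestTypeParams | None,
    constants: GlobalConstants,
    pasture_share: float,
) -> list[Cohort] | None:
    """New cohort(s) for a converted slice, or None if the event is a no-op.

    Degradation rule: forest observed as regrowth without prior clearing
    becomes degraded forest (carbon of fixed-age regrowth, soil intact);
    degraded forest observed as regrowth again stays put, and observed as
    forest it recovers along the curve from its equivalent age. Land
    observed as forest/regrowth after agriculture or other vegetation is
    seeded as a regrowth cohort at the equivalent age of its current
    carbon, avoiding fictitious instantaneous uptake.
    """
    cls = source.land_class

    if target == "forest" or target == "regrowth":
        if cls in ("forest", "regrowth") and not (
            cls == "forest" and target == "regrowth"
        ):
            return None
        if cls == "forest":  # target regrowth
            if not source.ever_cleared:
                return [
                    Cohort(
                        "degraded", frac, ftp.degraded_equiv_age,
                        degraded_agc(ftp), source.soil, source.ever_cleared,
                    )
                ]
            age = equivalent_age(source.agc, ftp)
            return [
                Cohort(
                    "regrowth", frac, age, agb_regrowth(age, ftp),
                    source.soil, source.ever_cleared,
                )
            ]
        if cls == "degraded":
            if target == "regrowth":
                return None
            age = ftp.degraded_equiv_age
            return [
                Cohort(
                    "regrowth", frac, age, agb_regrowth(age, ftp),
                    source.soil, source.ever_cleared,
                )
            ]
        # agriculture / pasture / other_vegetation / nonvegetated
        age = equivalent_age(source.agc, ftp)
        return [
            Cohort(
                "regrowth", frac, age, agb_regrowth(age, ftp),
                source.soil, source.ever_cleared,
            )
        ]

    if target == "agriculture":
        if cls in ("agriculture", "pasture"):
            return None
        out = []
        ag_frac = frac * (1.0 - pasture_share)
        if ag_frac > _FRAC_EPS:
            out.append(
                Cohort(
                    "agriculture", ag_frac, 0.0, constants.agri_agc,
                    source.soil, True,
                )
            )
        if frac - ag_frac > _FRAC_EPS:
            out.append(
                Cohort(
                    "pasture", frac - ag_frac, 0.0, constants.agri_agc,
                    source.soil, True,
                )
            )
        return out

    if target == "other_vegetation":
        if cls == "other_vegetation":
            return None
        return [
            Cohort(
                "other_vegetation", frac, 0.0, constants.other_veg_agc,
                source.soil, source.ever_cleared,
            )
        ]

    if target == "nonvegetated":
        if cls == "nonvegetated":
            return None
        cleared = source.ever_cleared or cls in ("forest", "regrowth", "degraded")
        return [Cohort("nonvegetated", frac, 0.0, 0.0, source.soil, cleared)]

    raise ValueError(f"unknown target cover class {target!r}")


def step_year(
    cohorts: list[Cohort],
    events: Sequence[ConversionEvent],
    ftp: ForestTypeParams | None,
    constants: GlobalConstants,
    pasture_share: float = 0.0,
) -> list[Cohort]:
    """Advance one year: age and recover every cohort, then apply this
    year's conversion events. Area fractions are conserved exactly."""
    before = sum(c.area_fraction for c in cohorts)
    for cohort in cohorts:
        _evolve(cohort, ftp, constants)
    created: list[Cohort] = []
    for event in events:
        frac = min(event.area_fraction, event.cohort.area_fraction)
        if frac <= _FRAC_EPS:
            continue
        pieces = _converted(
            event.cohort, frac, event.target, ftp, constants, pasture_share
        )
        if pieces is None:
            continue
        event.cohort.area_fraction -= frac
        created.extend(pieces)
    cohorts = [c for c in cohorts if c.area_fraction > _FRAC_EPS] + created
    after = sum(c.area_fraction for c in cohorts)
    if abs(after - before) > _AREA_TOL:
        raise RuntimeError(
            f"cohort area not conserved: {before:.12f} -> {after:.12f}"
        )
    return cohorts


def _total_stock(
    cohorts: Iterable[Cohort], area_ha: float, ftp: ForestTypeParams | None
) -> float:
    """Total pixel carbon stock, tC (shoots + roots + soil)."""
    return area_ha * sum(
        c.area_fraction * pixel_stock(c.agc, c.soil, ftp) for c in cohorts
    )


def run_pixel(
    pixel: PixelRecord,
    params: ParamSet,
    scenario=None,
    init: InitConfig | None = None,
    decade_years: int = 10,
    cohort_rule: str = "uniform",
) -> list[EmissionsResult]:
    """Run one pixel through both decades, carrying state over.

    Never-forested pixels (no epoch observed as forest or regrowth) carry
    zero land-use-change flux by construction. The per-decade mass-balance
    identity period_total = (stock_start - stock_end) * 44/12 holds exactly.
    """
    constants = params.constants
    pasture_share = float(getattr(scenario, "pasture_share", 0.0) or 0.0)
    ftp = params[pixel.forest_type] if pixel.forest_type is not None else None
    cohorts = init_state(pixel, params, init)

    if not pixel.ever_forested:
        stock = _total_stock(cohorts, pixel.area_ha, ftp)
        return [
            EmissionsResult(
                pixel.pixel_id, period, np.zeros(decade_years), 0.0, stock, stock
            )
            for period in PERIODS
        ]

    results = []
    covers = [getattr(pixel, col) for col in EPOCH_COLUMNS]
    for period, (cover_start, cover_end) in zip(
        PERIODS, zip(covers[:-1], covers[1:])
    ):
        schedule = dict(
            expand_transition(cover_start, cover_end, decade_years, cohort_rule)
        )
        sources = list(cohorts)
        source_areas = [c.area_fraction for c in sources]
        stock_start = _total_stock(cohorts, pixel.area_ha, ftp)
        stock_prev = stock_start
        fluxes = np.zeros(decade_years)
        for year in range(1, decade_years + 1):
            events = []
            if year in schedule:
                events = [
                    ConversionEvent(c, a * schedule[year], cover_end)
                    for c, a in zip(sources, source_areas)
                ]
            cohorts = step_year(cohorts, events, ftp, constants, pasture_share)
            stock_now = _total_stock(cohorts, pixel.area_ha, ftp)
            fluxes[year - 1] = (stock_prev - stock_now) * constants.co2_per_c
            stock_prev = stock_now
        results.append(
            EmissionsResult(
                pixel.pixel_id,
                period,
                fluxes,
                (stock_start - stock_prev) * constants.co2_per_c,
                stock_start,
                stock_prev,
            )
        )
    return results


@dataclass(frozen=True)
class GridResult:
    """Per-pixel and national emissions for both decades."""

    pixels: pd.DataFrame  # one row per pixel x period
    annual: pd.DataFrame  # one row per pixel x period x year
    national: pd.DataFrame  # one row per period

    def national_total(self, period: str) -> float:
        row = self.national[self.national["period"] == period]
        return float(row["total_tco2"].iloc[0])


GRID_COLUMNS = (
    "pixel_id",
    "area_ha",
    "forest_type",
    "agb_biomass_t_ha",
    "soc_ref",
    "department",
    "municipality",
    "cover_1990",
    "cover_2000",
    "cover_2010",
)


def validate_grid(grid: pd.DataFrame) -> None:
    """Raise with offending pixel ids on any structural violation."""
    missing = [c for c in GRID_COLUMNS if c not in grid.columns and c != "agb_biomass_t_ha"]
    if missing:
        raise ValueError(f"grid is missing columns: {missing}")
    if grid["pixel_id"].duplicated().any():
        dupes = grid.loc[grid["pixel_id"].duplicated(), "pixel_id"].tolist()
        raise ValueError(f"duplicate pixel ids: {dupes[:10]}")
    if (grid["area_ha"] <= 0).any():
        bad = grid.loc[grid["area_ha"] <= 0, "pixel_id"].tolist()
        raise ValueError(f"non-positive area for pixels: {bad[:10]}")
    for col in EPOCH_COLUMNS:
        bad = ~grid[col].isin(COVER_CLASSES)
        if bad.any():
            raise ValueError(
                f"invalid {col} classes for pixels: "
                f"{grid.loc[bad, 'pixel_id'].tolist()[:10]}"
            )
    forested = grid[list(EPOCH_COLUMNS)].isin(FORESTED_CLASSES).any(axis=1)
    no_type = forested & grid["forest_type"].isna()
    if no_type.any():
        raise ValueError(
            "forest_type missing for forested pixels: "
            f"{grid.loc[no_type, 'pixel_id'].tolist()[:10]}"
        )


def run_grid(
    grid: pd.DataFrame,
    params: ParamSet,
    scenario=None,
    init: InitConfig | None = None,
    decade_years: int = 10,
    cohort_rule: str = "uniform",
) -> GridResult:
    """Run the engine over a validated pixel grid and aggregate nationally."""
    validate_grid(grid)
    pixel_rows = []
    annual_rows = []
    for row in grid.to_dict("records"):
        pixel = PixelRecord.from_row(row)
        for res in run_pixel(
            pixel, params, scenario, init, decade_years, cohort_rule
        ):
            avg_annual = res.period_total / decade_years
            pixel_rows.append(
                {
                    "pixel_id": pixel.pixel_id,
                    "period": res.period,
                    "department": pixel.department,
                    "municipality": pixel.municipality,
                    "area_ha": pixel.area_ha,
                    "total_tco2": res.period_total,
                    "avg_annual_tco2": avg_annual,
                    "flux_tco2_km2_yr": avg_annual / (pixel.area_ha / 100.0),
                    "stock_start_tc": res.stock_start_tc,
                    "stock_end_tc": res.stock_end_tc,
                }
            )
            for year, flux in enumerate(res.annual_net_flux, start=1):
                annual_rows.append(
                    {
                        "pixel_id": pixel.pixel_id,
                        "period": res.period,
                        "year": year,
                        "flux_tco2": flux,
                    }
                )
    pixels = pd.DataFrame(pixel_rows)
    annual = pd.DataFrame(annual_rows)
    national = (
        pixels.groupby("period", as_index=False)["total_tco2"]
        .sum()
        .assign(avg_annual_tco2=lambda d: d["total_tco2"] / decade_years)
    )
    check = annual.groupby("period")["flux_tco2"].sum()
    for period in national["period"]:
        total = national.loc[national["period"] == period, "total_tco2"].iloc[0]
        if abs(check[period] - total) > max(1.0, abs(total)) * 1e-9:
            raise RuntimeError(f"aggregation mismatch in period {period}")
    return GridResult(pixels=pixels, annual=annual, national=national)
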