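"""Aggregation and indicator reporting.

Pixel-level fluxes are rolled up to departments, municipalities and the
national total; per-capita (tCO2/person/yr) and per-GDP (kg CO2 per 1990
Boliviano) indicators use mid-period denominators. Pixels are classified as
emitting, neutral or absorbing using a +/-10 tCO2/km2/yr neutral band, and
municipalities absorbing at least 1 tCO2/person/yr count as significant
sinks.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "aggregate",
    "per_capita",
    "per_gdp",
    "classify_pixels",
    "municipal_sinks",
    "national_population",
    "national_gdp",
    "annual_forest_loss",
    "regeneration_share",
    "summary_table",
]

NEUTRAL_BAND = 10.0  # tCO2/km2/yr, inclusive on both sides
SINK_THRESHOLD = 1.0  # tCO2/person/yr, inclusive

_LEVEL_COLUMN = {"department": "department", "municipality": "municipality"}


def aggregate(
    pixels: pd.DataFrame, level: str = "department", decade_years: int = 10
) -> pd.DataFrame:
    """Average annual net emissions per admin unit and national shares.

    ``pixels`` is the per-pixel x period table from the engine (needs
    ``department``/``municipality``, ``total_tco2``, ``period``). Unit
    totals sum exactly to the national total; shares are percentages of it.
    """
    if level == "national":
        out = pixels.groupby("period", as_index=False)["total_tco2"].sum()
        out["unit"] = "national"
        out["avg_annual_tco2"] = out["total_tco2"] / decade_years
        out["share_pct"] = 100.0
        return out[["unit", "period", "avg_annual_tco2", "share_pct"]]
    try:
        col = _LEVEL_COLUMN[level]
    except KeyError:
        raise ValueError(f"unknown aggregation level {level!r}") from None
    unmapped = pixels[col].isna() | (pixels[col].astype(str) == "")
    if unmapped.any():
        raise ValueError(
            f"pixels not mapped to a {level}: "
            f"{pixels.loc[unmapped, 'pixel_id'].tolist()[:10]}"
        )
    grouped = (
        pixels.groupby([col, "period"], as_index=False)["total_tco2"]
        .sum()
        .rename(columns={col: "unit"})
        .sort_values(["period", "unit"], kind="mergesort")
        .reset_index(drop=True)
    )
    grouped["avg_annual_tco2"] = grouped["total_tco2"] / decade_years
    national = grouped.groupby("period")["total_tco2"].transform("sum")
    grouped["share_pct"] = np.where(
        national != 0, 100.0 * grouped["total_tco2"] / national, 0.0
    )
    return grouped[["unit", "period", "avg_annual_tco2", "share_pct"]]


def per_capita(annual_tco2: float, population: float) -> float:
    """Average annual emissions per person, tCO2/person/yr."""
    if population <= 0:
        raise ValueError("population must be positive for per-capita output")
    return annual_tco2 / population


def per_gdp(annual_tco2: float, gdp_thousand_bs: float) -> float:
    """Emissions per unit of GDP, kg CO2 per (1990) Boliviano.

    annual_tco2 * 1000 kg/t divided by gdp * 1000 Bs reduces to the plain
    ratio annual_tco2 / gdp_thousand_bs.
    """
    if gdp_thousand_bs <= 0:
        raise ValueError("GDP must be positive for per-GDP output")
    return annual_tco2 / gdp_thousand_bs


def classify_pixels(
    flux_per_km2: Sequence[float], band: float = NEUTRAL_BAND
) -> tuple[np.ndarray, dict[str, float]]:
    """Classify per-pixel annual flux densities (tCO2/km2/yr).

    Neutral means within [-band, band] inclusive. Returns the class array
    and class frequencies (fractions summing to 1).
    """
    flux = np.asarray(flux_per_km2, dtype=float)
    if not np.all(np.isfinite(flux)):
        raise ValueError("flux densities must be finite")
    classes = np.where(
        flux > band, "emitting", np.where(flux < -band, "absorbing", "neutral")
    )
    freqs = {
        label: float(np.mean(classes == label))
        for label in ("emitting", "neutral", "absorbing")
    }
    return classes, freqs


def municipal_sinks(
    per_capita_values: Iterable[float], threshold: float = SINK_THRESHOLD
) -> int:
    """Count municipalities absorbing at least ``threshold`` tCO2/person/yr
    (per-capita emissions <= -threshold, inclusive)."""
    values = np.asarray(list(per_capita_values), dtype=float)
    return int(np.sum(values <= -threshold))


def _national_stat(admin: pd.DataFrame, period: str, column: str) -> float:
    national = admin[(admin["level"] == "national") & (admin["period"] == period)]
    if len(national):
        return float(national[column].iloc[0])
    depts = admin[(admin["level"] == "department") & (admin["period"] == period)]
    if not len(depts):
        raise ValueError(f"no admin statistics for period {period!r}")
    return float(depts[column].sum())


def national_population(admin: pd.DataFrame, period: str) -> float:
    return _national_stat(admin, period, "population")


def national_gdp(admin: pd.DataFrame, period: str) -> float:
    return _national_stat(admin, period, "gdp_thousand_bs")


def annual_forest_loss(
    forest_area_start: float, forest_area_end: float, years: int
) -> float:
    """Average annual loss of forest area, ha/yr (negative = net gain)."""
    if years <= 0:
        raise ValueError("years must be positive")
    return (forest_area_start - forest_area_end) / years


def regeneration_share(
    regenerating_area: float, deforested_area: float
) -> float:
    """Share of cumulatively deforested area currently regenerating."""
    if deforested_area <= 0:
        raise ValueError("deforested area must be positive")
    return regenerating_area / deforested_area


def summary_table(
    pixels: pd.DataFrame, admin: pd.DataFrame, decade_years: int = 10
) -> pd.DataFrame:
    """National summary per decade: totals, per-capita and per-GDP rates."""
    rows = []
    for period, grp in pixels.groupby("period"):
        total = float(grp["total_tco2"].sum())
        annual = total / decade_years
        pop = national_population(admin, period)
        gdp = national_gdp(admin, period)
        rows.append(
            {
                "period": period,
                "total_tco2": total,
                "avg_annual_tco2": annual,
                "mid_period_population": pop,
                "per_capita_tco2": per_capita(annual, pop),
                "mid_period_gdp_thousand_bs": gdp,
                "per_gdp_kg_bs": per_gdp(annual, gdp),
            }
        )
    return pd.DataFrame(rows)
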