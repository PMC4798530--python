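"""Synthetic landscape generator.

Stands in for the national GIS inputs the analysis was designed around: a
10x10 km pixel grid with a land-cover class per epoch, a predominant forest
type and mapped biomass/soil carbon per pixel, per-type intact-pixel
biomass samples (the reference distributions for mature carbon), and
mid-period population/GDP per department. Biomass is drawn from a lognormal
per forest type (the intact-forest distributions are right-skewed); cover
classes evolve by per-pixel sampling from decadal transition matrices,
including the "odd" transitions (e.g. other vegetation observed as forest a
decade later) seen in the satellite record.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .bookkeeping import COVER_CLASSES, EPOCH_COLUMNS, PERIODS

__all__ = [
    "LandscapeConfig",
    "gen_landscape",
    "gen_national_like",
    "expected_cover_areas",
    "expected_mean_cap",
]

_ROW_TOL = 1e-9


@dataclass(frozen=True)
class LandscapeConfig:
    """Statistical description of a synthetic landscape."""

    n_pixels: int
    forest_type_shares: Mapping[str, float]
    biomass_median_t_ha: Mapping[str, float]
    cover_shares_1990: Mapping[str, float]
    transitions: Mapping[str, Mapping[str, Mapping[str, float]]]
    department_weights: Mapping[str, float]
    population: Mapping[str, Mapping[str, float]]  # period -> dept -> persons
    gdp_thousand_bs: Mapping[str, Mapping[str, float]]  # period -> dept
    pixel_area_ha: float = 10_000.0
    biomass_log_sd: float = 0.30
    soc_range: tuple[float, float] = (30.0, 140.0)
    municipalities_per_department: int = 3
    n_biomass_samples_per_type: int = 200
    seed: int = 0

    def validate(self) -> None:
        if self.n_pixels <= 0:
            raise ValueError("n_pixels must be positive")
        for label, shares in (
            ("forest_type_shares", self.forest_type_shares),
            ("cover_shares_1990", self.cover_shares_1990),
            ("department_weights", self.department_weights),
        ):
            total = sum(shares.values())
            if abs(total - 1.0) > 1e-6:
                raise ValueError(f"{label} sum to {total}, expected 1")
            if any(v < 0 for v in shares.values()):
                raise ValueError(f"{label} contain negative shares")
        for cover in self.cover_shares_1990:
            if cover not in COVER_CLASSES:
                raise ValueError(f"unknown cover class {cover!r}")
        for period, matrix in self.transitions.items():
            for source, row in matrix.items():
                total = sum(row.values())
                if abs(total - 1.0) > _ROW_TOL:
                    raise ValueError(
                        f"transition row {period}/{source} sums to {total}"
                    )
                if any(p < 0 for p in row.values()):
                    raise ValueError(
                        f"transition row {period}/{source} has negative entries"
                    )


def _row_vector(row: Mapping[str, float]) -> np.ndarray:
    return np.array([row.get(c, 0.0) for c in COVER_CLASSES])


def _sample_class(
    rng: np.random.Generator, probs: np.ndarray, n: int
) -> np.ndarray:
    return rng.choice(len(COVER_CLASSES), size=n, p=probs / probs.sum())


def gen_landscape(
    config: LandscapeConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate (grid, biomass samples, admin stats); deterministic per seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_pixels

    type_names = list(config.forest_type_shares)
    type_probs = np.array([config.forest_type_shares[t] for t in type_names])
    forest_type = rng.choice(type_names, size=n, p=type_probs / type_probs.sum())

    cover_probs = _row_vector(config.cover_shares_1990)
    cover_idx = {EPOCH_COLUMNS[0]: _sample_class(rng, cover_probs, n)}
    prev = cover_idx[EPOCH_COLUMNS[0]]
    for period, epoch_col in zip(PERIODS, EPOCH_COLUMNS[1:]):
        matrix = np.stack(
            [
                _row_vector(config.transitions[period][c])
                for c in COVER_CLASSES
            ]
        )
        nxt = np.empty(n, dtype=int)
        for i, source in enumerate(COVER_CLASSES):
            mask = prev == i
            if mask.any():
                nxt[mask] = _sample_class(rng, matrix[i], int(mask.sum()))
        cover_idx[epoch_col] = nxt
        prev = nxt

    medians = np.array(
        [config.biomass_median_t_ha[t] for t in forest_type]
    )
    biomass = medians * np.exp(
        rng.normal(0.0, config.biomass_log_sd, size=n)
    )
    soc = rng.uniform(*config.soc_range, size=n)

    dept_names = list(config.department_weights)
    dept_probs = np.array([config.department_weights[d] for d in dept_names])
    department = rng.choice(dept_names, size=n, p=dept_probs / dept_probs.sum())
    muni_index = rng.integers(
        1, config.municipalities_per_department + 1, size=n
    )
    municipality = np.array(
        [f"{d}_m{m}" for d, m in zip(department, muni_index)]
    )

    grid = pd.DataFrame(
        {
            "pixel_id": [f"px{i:06d}" for i in range(n)],
            "area_ha": config.pixel_area_ha,
            "forest_type": forest_type,
            "agb_biomass_t_ha": biomass,
            "soc_ref": soc,
            "department": department,
            "municipality": municipality,
        }
    )
    for col, idx in cover_idx.items():
        grid[col] = np.array(COVER_CLASSES)[idx]
    # Forest type is only meaningful where land is ever forested.
    forested = grid[list(EPOCH_COLUMNS)].isin(("forest", "regrowth")).any(axis=1)
    grid.loc[~forested, "forest_type"] = None

    # Per-type reference samples from nearly intact pixels (Fig-1-like),
    # plus a tail of disturbed pixels that the intact flag excludes.
    m = config.n_biomass_samples_per_type
    frames = []
    for t in type_names:
        intact = config.biomass_median_t_ha[t] * np.exp(
            rng.normal(0.0, config.biomass_log_sd, size=m)
        )
        disturbed = 0.4 * config.biomass_median_t_ha[t] * np.exp(
            rng.normal(0.0, config.biomass_log_sd, size=max(1, m // 5))
        )
        frames.append(
            pd.DataFrame(
                {
                    "forest_type": t,
                    "biomass_t_ha": np.concatenate([intact, disturbed]),
                    "intact_flag": [True] * m + [False] * max(1, m // 5),
                }
            )
        )
    biomass_table = pd.concat(frames, ignore_index=True)

    admin_rows = []
    k = config.municipalities_per_department
    for period in PERIODS:
        pop = config.population[period]
        gdp = config.gdp_thousand_bs[period]
        admin_rows.append(
            {
                "unit": "national",
                "level": "national",
                "department": "",
                "period": period,
                "population": float(sum(pop.values())),
                "gdp_thousand_bs": float(sum(gdp.values())),
            }
        )
        for dept in dept_names:
            admin_rows.append(
                {
                    "unit": dept,
                    "level": "department",
                    "department": dept,
                    "period": period,
                    "population": float(pop[dept]),
                    "gdp_thousand_bs": float(gdp[dept]),
                }
            )
            for j in range(1, k + 1):
                admin_rows.append(
                    {
                        "unit": f"{dept}_m{j}",
                        "level": "municipality",
                        "department": dept,
                        "period": period,
                        "population": float(pop[dept]) / k,
                        "gdp_thousand_bs": float(gdp[dept]) / k,
                    }
                )
    admin = pd.DataFrame(admin_rows)
    return grid, biomass_table, admin


def expected_cover_areas(config: LandscapeConfig) -> pd.DataFrame:
    """Expected area (ha) per cover class at each epoch, from the chain of
    transition matrices — the analytic counterpart of a generated grid."""
    total_ha = config.n_pixels * config.pixel_area_ha
    shares = _row_vector(config.cover_shares_1990)
    rows = [dict(zip(COVER_CLASSES, shares * total_ha), epoch=1990)]
    for period, epoch in zip(PERIODS, (2000, 2010)):
        matrix = np.stack(
            [_row_vector(config.transitions[period][c]) for c in COVER_CLASSES]
        )
        shares = shares @ matrix
        rows.append(dict(zip(COVER_CLASSES, shares * total_ha), epoch=epoch))
    return pd.DataFrame(rows).set_index("epoch")


def expected_mean_cap(
    config: LandscapeConfig, carbon_fraction: float = 0.5
) -> float:
    """Forest-share-weighted mean mature aboveground carbon, tC/ha."""
    return carbon_fraction * sum(
        share * config.biomass_median_t_ha[t]
        for t, share in config.forest_type_shares.items()
    )


# ---------------------------------------------------------------------------
# National-like preset
# ---------------------------------------------------------------------------

# Forest-type composition: Amazon forest over a third of all forest;
# Chaco, Chiquitano and Yungas about a sixth each; dry inter-Andean and
# Andean forest together 0.3%. Median intact biomass per type is chosen so
# the share-weighted mean aboveground carbon is 114 tC/ha.
_NATIONAL_TYPE_SHARES = {
    "amazon": 0.360,
    "chaco": 0.170,
    "chiquitano": 0.160,
    "yungas": 0.150,
    "flooded_beni": 0.070,
    "pantanal": 0.050,
    "tucumano": 0.037,
    "dry_inter_andean": 0.002,
    "andean": 0.001,
}
_NATIONAL_BIOMASS_MEDIANS = {
    "amazon": 290.0,
    "chaco": 140.0,
    "chiquitano": 180.0,
    "yungas": 270.0,
    "flooded_beni": 200.0,
    "pantanal": 160.0,
    "tucumano": 220.0,
    "dry_inter_andean": 80.0,
    "andean": 120.0,
}

# National land balance, million hectares. Forest cover 56.8 (1990) ->
# 55.0 (2000) -> 52.6 (2010); agriculture on previously forested land
# 1.9 -> 3.3 -> 5.2. Gross flows are chosen to reproduce that trajectory,
# including the odd transitions (forest straight to regrowth or other
# vegetation, other vegetation observed as forest a decade later).
_AREAS_1990_MHA = {
    "forest": 56.8,
    "agriculture": 1.9,
    "regrowth": 0.7,
    "other_vegetation": 38.46,
    "nonvegetated": 12.0,
}
_FLOWS_MHA = {
    "1990-2000": {
        ("forest", "agriculture"): 1.50,
        ("forest", "regrowth"): 0.40,
        ("forest", "other_vegetation"): 0.30,
        ("agriculture", "regrowth"): 0.60,
        ("regrowth", "forest"): 0.25,
        ("regrowth", "agriculture"): 0.05,
        ("other_vegetation", "forest"): 0.15,
        ("other_vegetation", "agriculture"): 0.50,
    },
    "2000-2010": {
        ("forest", "agriculture"): 2.30,
        ("forest", "regrowth"): 0.80,
        ("forest", "other_vegetation"): 1.27,
        ("agriculture", "regrowth"): 0.75,
        ("regrowth", "forest"): 0.64,
        ("regrowth", "agriculture"): 0.20,
        ("other_vegetation", "forest"): 1.33,
        ("other_vegetation", "agriculture"): 0.30,
    },
}

_DEPARTMENTS = {
    "santa_cruz": 0.34,
    "beni": 0.19,
    "la_paz": 0.12,
    "potosi": 0.11,
    "pando": 0.06,
    "cochabamba": 0.05,
    "chuquisaca": 0.05,
    "oruro": 0.05,
    "tarija": 0.03,
}
_POP_SHARES = {
    "la_paz": 0.28,
    "santa_cruz": 0.26,
    "cochabamba": 0.17,
    "potosi": 0.08,
    "chuquisaca": 0.06,
    "oruro": 0.05,
    "tarija": 0.05,
    "beni": 0.04,
    "pando": 0.01,
}
_NATIONAL_POPULATION = {"1990-2000": 6_987_201.0, "2000-2010": 8_873_150.0}
_NATIONAL_GDP = {"1990-2000": 18_626_778.0, "2000-2010": 26_657_738.0}


def _flow_matrices() -> dict[str, dict[str, dict[str, float]]]:
    transitions: dict[str, dict[str, dict[str, float]]] = {}
    areas = dict(_AREAS_1990_MHA)
    for period in PERIODS:
        matrix: dict[str, dict[str, float]] = {}
        outflow: dict[str, float] = {c: 0.0 for c in COVER_CLASSES}
        inflow: dict[str, float] = {c: 0.0 for c in COVER_CLASSES}
        for (src, dst), mha in _FLOWS_MHA[period].items():
            outflow[src] += mha
            inflow[dst] += mha
        for src in COVER_CLASSES:
            row = {c: 0.0 for c in COVER_CLASSES}
            for (s, dst), mha in _FLOWS_MHA[period].items():
                if s == src:
                    row[dst] = mha / areas[src]
            row[src] = 1.0 - sum(row.values())
            matrix[src] = row
        transitions[period] = matrix
        areas = {
            c: areas[c] - outflow[c] + inflow[c] for c in COVER_CLASSES
        }
    return transitions


def gen_national_like(n_pixels: int = 800, seed: int = 0) -> LandscapeConfig:
    """Preset whose expected forest areas scale to the national 56.8 /
    55.0 / 52.6 Mha trajectory and whose share-weighted mean intact carbon
    is 114 tC/ha, at a reduced pixel count for integration tests."""
    total = sum(_AREAS_1990_MHA.values())
    cover_shares = {c: a / total for c, a in _AREAS_1990_MHA.items()}
    population = {
        p: {d: share * _NATIONAL_POPULATION[p] for d, share in _POP_SHARES.items()}
        for p in PERIODS
    }
    gdp = {
        p: {d: share * _NATIONAL_GDP[p] for d, share in _POP_SHARES.items()}
        for p in PERIODS
    }
    return LandscapeConfig(
        n_pixels=n_pixels,
        forest_type_shares=dict(_NATIONAL_TYPE_SHARES),
        biomass_median_t_ha=dict(_NATIONAL_BIOMASS_MEDIANS),
        cover_shares_1990=cover_shares,
        transitions=_flow_matrices(),
        department_weights=dict(_DEPARTMENTS),
        population=population,
        gdp_thousand_bs=gdp,
        seed=seed,
    )
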