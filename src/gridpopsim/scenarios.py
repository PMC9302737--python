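"""Census degradation scenarios.

Sixteen degraded household populations (4 reference years x 4 undercount
levels) are each aggregated to the two areal-unit levels, giving the 32
census inputs the disaggregation model trains on. Outdatedness removes
households built after the reference year; undercount removes a fixed
fraction of households per stratum uniformly at random (no spatial pattern),
with the retained count deterministic: floor((1 - rate) * N).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grids import GridSpec
from .synthetic import STRATA, SimulationConfig, ZoneMap, derive_rng, simulate_households, delineate_zones

#: simulated census undercount rates per stratum (slum, non-slum, rural)
INACCURACY_RATES: dict[str, dict[str, float]] = {
    "none": {"urban_slum": 0.0, "urban_nonslum": 0.0, "rural": 0.0},
    "low": {"urban_slum": 0.10, "urban_nonslum": 0.02, "rural": 0.02},
    "medium": {"urban_slum": 0.30, "urban_nonslum": 0.05, "rural": 0.05},
    "high": {"urban_slum": 0.60, "urban_nonslum": 0.10, "rural": 0.10},
}

INACCURACY_LEVELS = ("none", "low", "medium", "high")
AGGREGATION_LEVELS = ("small_zone", "large_zone")


@dataclass(frozen=True)
class ScenarioSpec:
    """One of the 32 census-input scenarios."""

    reference_year: int
    inaccuracy: str
    aggregation: str
    rates: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.inaccuracy not in INACCURACY_LEVELS:
            raise ValueError(f"unknown inaccuracy level {self.inaccuracy!r}")
        if self.aggregation not in AGGREGATION_LEVELS:
            raise ValueError(f"unknown aggregation level {self.aggregation!r}")
        if not self.rates:
            object.__setattr__(self, "rates", dict(INACCURACY_RATES[self.inaccuracy]))
        if any(not 0.0 <= r <= 1.0 for r in self.rates.values()):
            raise ValueError("undercount rates must lie in [0, 1]")

    @property
    def tag(self) -> str:
        agg = "small" if self.aggregation == "small_zone" else "large"
        return f"y{self.reference_year}_i{self.inaccuracy}_a{agg}"


def filter_by_year(households: pd.DataFrame, reference_year: int) -> pd.DataFrame:
    """Keep households with build_year <= reference_year (census outdatedness)."""
    return households[households["build_year"] <= reference_year].copy()


def retained_count(n: int, rate: float) -> int:
    """Households kept when an undercount rate is applied to n households."""
    return int(np.floor((1.0 - rate) * n))


def apply_undercount(
    households: pd.DataFrame,
    rates: dict,
    seed: int,
    pool_nonslum_rural: bool = False,
) -> pd.DataFrame:
    """Remove a seed-independent *count* of households per stratum at random.

    For each stratum with N households and rate r, exactly
    ``floor((1 - r) * N)`` households are retained, chosen uniformly at
    random, so undercount has no spatial pattern. With
    ``pool_nonslum_rural`` the non-slum and rural strata are pooled before
    the count is computed (their rates must then agree), which reproduces
    the alternative rounding arithmetic seen in pooled census tabulations.
    """
    if any(not 0.0 <= r <= 1.0 for r in rates.values()):
        raise ValueError("undercount rates must lie in [0, 1]")
    rng = derive_rng(seed, "undercount")
    keep_idx = []
    if pool_nonslum_rural:
        if rates["urban_nonslum"] != rates["rural"]:
            raise ValueError("pooled removal needs equal non-slum and rural rates")
        groups = [("urban_slum",), ("urban_nonslum", "rural")]
    else:
        groups = [(s,) for s in STRATA]
    for strata_group in groups:
        members = households.index[households["stratum"].isin(strata_group)].to_numpy()
        if members.size == 0:
            continue
        rate = rates[strata_group[0]]
        n_keep = retained_count(members.size, rate)
        keep_idx.append(rng.choice(members, size=n_keep, replace=False))
    if not keep_idx:
        return households.iloc[0:0].copy()
    kept = np.concatenate(keep_idx)
    return households.loc[np.sort(kept)].copy()


def make_census(households: pd.DataFrame, zones: ZoneMap, grid: GridSpec) -> pd.DataFrame:
    """Aggregate a household table to per-zone census counts.

    Returns a ZoneTable: zone_id, population, area_cells, settled_cells.
    area_cells counts every grid cell in the zone (1 cell = 1 ha);
    settled_cells counts cells holding at least one of *these* households.
    """
    labels = zones.labels
    n_zones = zones.n_zones
    area = np.bincount(labels.ravel(), minlength=n_zones + 1)[1:]
    if (area == 0).any():
        raise ValueError("zone labels must be contiguous 1..K with no empty label")
    pop = np.zeros(n_zones, dtype=np.int64)
    settled = np.zeros(n_zones, dtype=np.int64)
    if not households.empty:
        row, col = grid.cell_of(households["x"].to_numpy(), households["y"].to_numpy())
        z = labels[row, col]
        if (z == 0).any():
            raise ValueError("household cell carries no zone label")
        pop = np.bincount(z, weights=households["persons"].to_numpy(), minlength=n_zones + 1)[1:].astype(np.int64)
        cells = np.zeros(grid.shape, dtype=bool)
        cells[row, col] = True
        settled = np.bincount(labels[cells], minlength=n_zones + 1)[1:]
    return pd.DataFrame(
        {
            "zone_id": np.arange(1, n_zones + 1, dtype=np.int64),
            "population": pop,
            "area_cells": area.astype(np.int64),
            "settled_cells": settled.astype(np.int64),
        }
    )


@dataclass
class ScenarioBundle:
    """Everything the 32-scenario run shares: truth plus degraded inputs."""

    config: SimulationConfig
    households: pd.DataFrame
    strata: np.ndarray
    zones: dict               # level -> ZoneMap
    degraded: dict            # (year, inaccuracy) -> household table
    censuses: list            # [(ScenarioSpec, ZoneTable), ...]


def scenario_matrix(
    config: SimulationConfig,
    seed: int | None = None,
    years=None,
    inaccuracy_levels=INACCURACY_LEVELS,
    aggregations=AGGREGATION_LEVELS,
    pool_nonslum_rural: bool = False,
) -> ScenarioBundle:
    """Build the full census-input matrix (default 4 x 4 x 2 = 32 entries).

    One truth population is simulated; each (year, inaccuracy) pair shares a
    single degraded household table across its two aggregation levels, so
    census totals agree between levels by construction. Degradation seeds
    derive from the master seed and the scenario labels, making every
    scenario reproducible in isolation.
    """
    config.validate()
    if seed is None:
        seed = config.seed
    if years is None:
        years = tuple(sorted(config.years, reverse=True))
    households, strata = simulate_households(config, seed)
    small, large = delineate_zones(households, config.grid, config.n_small, config.n_large, seed)
    zones = {"small_zone": small, "large_zone": large}

    degraded = {}
    censuses = []
    for year in years:
        aged = filter_by_year(households, year)
        for level in inaccuracy_levels:
            rates = INACCURACY_RATES[level]
            sub_seed = int(derive_rng(seed, "scenario", year, level).integers(0, 2**31))
            table = apply_undercount(aged, rates, sub_seed, pool_nonslum_rural)
            degraded[(year, level)] = table
            for agg in aggregations:
                spec = ScenarioSpec(reference_year=year, inaccuracy=level, aggregation=agg)
                censuses.append((spec, make_census(table, zones[agg], config.grid)))
    return ScenarioBundle(
        config=config,
        households=households,
        strata=strata,
        zones=zones,
        degraded=degraded,
        censuses=censuses,
    )
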