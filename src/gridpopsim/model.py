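"""Top-down Random-Forest dasymetric disaggregation.

Three phases, mirroring the standard unconstrained gridded-population
workflow:

A. summarise covariates per areal unit and fit a regression forest to the
   log population density of units with non-zero population (zero-population
   units are excluded before the log transform);
B. predict log density for every grid cell and back-transform by
   exponentiating the ensemble mean;
C. normalise predicted densities within each areal unit so cell estimates
   sum exactly to the unit's census count (pycnophylactic property), then
   multiply out to per-cell person counts.

Density uses the unit's *total* cell count as denominator (1 cell = 1 ha),
including unsettled cells — the unconstrained behaviour under study. No
settlement mask is applied, so every cell, settled or not, receives a
strictly positive predicted density; misallocation of population into
unsettled cells is a phenomenon of interest, not an error.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

from .synthetic import CovariateStack, ZoneMap

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ForestSettings:
    """Regression-forest hyperparameters (conventional defaults).

    ``max_features`` defaults to ceil(p/3) candidate covariates per split.
    """

    n_trees: int = 500
    max_features: int | None = None
    min_samples_leaf: int = 1

    def resolved_max_features(self, p: int) -> int:
        if self.max_features is not None:
            return min(self.max_features, p)
        return int(np.ceil(p / 3))


@dataclass
class DensityModel:
    """Trained forest plus the metadata needed to audit and reuse it."""

    forest: RandomForestRegressor
    covariate_names: list
    excluded_zones: list
    settings: ForestSettings
    seed: int

    @property
    def n_trees(self) -> int:
        return len(self.forest.estimators_)

    def metadata(self) -> dict:
        return {
            "n_trees": self.n_trees,
            "max_features": int(self.forest.max_features),
            "covariates": list(self.covariate_names),
            "excluded_zones": [int(z) for z in self.excluded_zones],
            "seed": int(self.seed),
        }


def zonal_features(cov: CovariateStack, zones: ZoneMap, census: pd.DataFrame) -> pd.DataFrame:
    """Per-zone covariate means, density, and log density.

    Zones with zero census population get ``excluded=True`` and NaN
    log_density; they take no part in model training.
    """
    labels = zones.labels
    if cov.layers.shape[1:] != labels.shape:
        raise ValueError(
            f"covariate grid {cov.layers.shape[1:]} does not match zone grid {labels.shape}"
        )
    n_zones = zones.n_zones
    census = census.sort_values("zone_id").reset_index(drop=True)
    if not np.array_equal(census["zone_id"].to_numpy(), np.arange(1, n_zones + 1)):
        raise ValueError("census must cover zone ids 1..K exactly")
    flat = labels.ravel()
    area = np.bincount(flat, minlength=n_zones + 1)[1:]
    out = {"zone_id": np.arange(1, n_zones + 1, dtype=np.int64)}
    for name, layer in zip(cov.names, cov.layers):
        sums = np.bincount(flat, weights=layer.ravel(), minlength=n_zones + 1)[1:]
        out[name] = sums / area
    pop = census["population"].to_numpy(dtype=np.float64)
    density = pop / census["area_cells"].to_numpy(dtype=np.float64)
    out["density"] = density
    out["excluded"] = pop <= 0
    log_density = np.full(n_zones, np.nan)
    pos = pop > 0
    log_density[pos] = np.log(density[pos])
    out["log_density"] = log_density
    return pd.DataFrame(out)


def train_density_model(
    features: pd.DataFrame,
    settings: ForestSettings | None = None,
    seed: int = 0,
) -> DensityModel:
    """Phase A: fit the forest to (zonal covariate means -> log density)."""
    settings = settings or ForestSettings()
    usable = features[~features["excluded"]]
    if len(usable) < 2:
        raise ValueError(f"need >= 2 zones with population, have {len(usable)}")
    cov_names = [
        c for c in features.columns if c not in ("zone_id", "density", "log_density", "excluded")
    ]
    if not cov_names:
        raise ValueError("need at least one covariate column")
    X = usable[cov_names].to_numpy(dtype=np.float64)
    y = usable["log_density"].to_numpy(dtype=np.float64)
    forest = RandomForestRegressor(
        n_estimators=settings.n_trees,
        max_features=settings.resolved_max_features(len(cov_names)),
        min_samples_leaf=settings.min_samples_leaf,
        bootstrap=True,
        random_state=int(seed) & 0x7FFFFFFF,
        n_jobs=1,
    )
    forest.fit(X, y)
    excluded = features.loc[features["excluded"], "zone_id"].tolist()
    if excluded:
        logger.info("excluded %d zero-population zones from training", len(excluded))
    return DensityModel(
        forest=forest,
        covariate_names=cov_names,
        excluded_zones=excluded,
        settings=settings,
        seed=int(seed),
    )


def predict_density(model: DensityModel, cov: CovariateStack) -> np.ndarray:
    """Phase B: per-cell density = exp(ensemble-mean log density); > 0 everywhere."""
    missing = [n for n in model.covariate_names if n not in cov.names]
    if missing:
        raise ValueError(f"covariate stack missing layers {missing}")
    shape = cov.layers.shape[1:]
    X = np.column_stack([cov[name].ravel() for name in model.covariate_names])
    log_density = model.forest.predict(X)
    return np.exp(log_density).reshape(shape)


def disaggregate(
    density: np.ndarray, zones: ZoneMap, census: pd.DataFrame
) -> np.ndarray:
    """Phase C: dasymetric redistribution preserving zone census counts.

    cell estimate = zone population * cell density / sum of zone densities.
    Zones with zero population yield all-zero cells; a zone whose predicted
    densities sum to zero but whose population is positive falls back to
    uniform disaggregation (with a warning).
    """
    labels = zones.labels
    if density.shape != labels.shape:
        raise ValueError("density raster and zone map shapes differ")
    n_zones = zones.n_zones
    census = census.sort_values("zone_id").reset_index(drop=True)
    if not np.array_equal(census["zone_id"].to_numpy(), np.arange(1, n_zones + 1)):
        raise ValueError("census must cover zone ids 1..K exactly")
    flat = labels.ravel()
    d = np.asarray(density, dtype=np.float64).ravel()
    zone_density = np.bincount(flat, weights=d, minlength=n_zones + 1)[1:]
    pop = census["population"].to_numpy(dtype=np.float64)

    degenerate = (zone_density <= 0) & (pop > 0)
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} zone(s) with zero predicted density but "
            "positive population: falling back to uniform disaggregation",
            stacklevel=2,
        )
        area = np.bincount(flat, minlength=n_zones + 1)[1:]
        for z in np.flatnonzero(degenerate):
            d[flat == z + 1] = 1.0
        zone_density = np.bincount(flat, weights=d, minlength=n_zones + 1)[1:]

    with np.errstate(invalid="ignore", divide="ignore"):
        factor = np.where(zone_density > 0, pop / np.where(zone_density > 0, zone_density, 1.0), 0.0)
    est = d * factor[flat - 1]
    return est.reshape(labels.shape)


def run_topdown(
    cov: CovariateStack,
    zones: ZoneMap,
    census: pd.DataFrame,
    settings: ForestSettings | None = None,
    seed: int = 0,
) -> tuple[np.ndarray, DensityModel]:
    """All three phases; returns the estimate raster and the trained model."""
    features = zonal_features(cov, zones, census)
    model = train_density_model(features, settings, seed)
    density = predict_density(model, cov)
    estimate = disaggregate(density, zones, census)
    return estimate, model
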