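"""Cell-level accuracy statistics.

Compares an estimate raster against the true population raster at block
scales k = 1..10 (100 m up to 1 km on the default grid), overall and within
urban-slum / urban-non-slum / rural strata:

* population-adjusted RMSE: RMSE of cell counts divided by the mean true
  cell population (dimensionless);
* density RMSE: RMSE of persons per hectare, a k x k block covering k**2 ha;
* bias and relative bias: mean signed error, raw and divided by the mean
  true population (negative = under-estimate);
* misallocated percentage: share of the estimated population placed in
  cells that are truly unsettled (no person-threshold applied here).

For the four error statistics, cells whose *estimated* population falls
below an inclusion threshold (default 1 person, applied at the evaluated
scale) are excluded, so millions of near-zero estimates in unsettled
hinterland do not dominate the assessment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grids import block_sum
from .synthetic import RURAL, STRATUM_CODES, STRATUM_NAMES, URBAN_NONSLUM, URBAN_SLUM

METRIC_NAMES = ("pop_adj_rmse", "density_rmse", "bias", "relative_bias", "misallocated_pct")

METRICS_COLUMNS = ["scenario", "scale_m", "stratum", "metric", "value", "n_cells"]


@dataclass(frozen=True)
class EvaluationConfig:
    scales: tuple = tuple(range(1, 11))
    inclusion_threshold: float = 1.0
    strata: tuple = ("urban_slum", "urban_nonslum", "rural")

    def __post_init__(self):
        if any(k < 1 for k in self.scales):
            raise ValueError("block factors must be >= 1")
        if self.inclusion_threshold < 0:
            raise ValueError("inclusion threshold must be >= 0")


def aggregate_blocks(raster: np.ndarray, k: int) -> np.ndarray:
    """Sum k x k blocks (ragged edges dropped); k = 1 is the identity."""
    return block_sum(np.asarray(raster, dtype=np.float64), k)


def _masked(est, truth, mask):
    est = np.asarray(est, dtype=np.float64)
    truth = np.asarray(truth, dtype=np.float64)
    if mask is None:
        mask = np.ones(est.shape, dtype=bool)
    if not mask.any():
        raise ValueError("mask selects no cells")
    return est[mask], truth[mask]


def pop_adjusted_rmse(est, truth, mask=None) -> float:
    """RMSE of cell counts as a proportion of the mean true cell population."""
    e, t = _masked(est, truth, mask)
    mean_truth = t.mean()
    if mean_truth <= 0:
        raise ValueError("mean true population over the mask is zero")
    return float(np.sqrt(np.mean((e - t) ** 2)) / mean_truth)


def density_rmse(est, truth, k=1, mask=None) -> float:
    """RMSE of population density per hectare; a k-block covers k**2 hectares."""
    e, t = _masked(est, truth, mask)
    return float(np.sqrt(np.mean(((e - t) / k**2) ** 2)))


def bias(est, truth, mask=None) -> float:
    """Mean signed error per cell (negative = under-estimate)."""
    e, t = _masked(est, truth, mask)
    return float(np.mean(e - t))


def relative_bias(est, truth, mask=None) -> float:
    """Bias divided by the mean true cell population."""
    e, t = _masked(est, truth, mask)
    mean_truth = t.mean()
    if mean_truth <= 0:
        raise ValueError("mean true population over the mask is zero")
    return float(np.mean(e - t) / mean_truth)


def misallocated_fraction(est, truth) -> float:
    """Percent of the estimated population placed in truly unsettled cells."""
    est = np.asarray(est, dtype=np.float64)
    truth = np.asarray(truth, dtype=np.float64)
    if est.shape != truth.shape:
        raise ValueError("rasters must share a shape")
    total = est.sum()
    if total <= 0:
        raise ValueError("estimate raster has zero total population")
    return float(100.0 * est[truth == 0].sum() / total)


def aggregate_strata(strata: np.ndarray, truth: np.ndarray, k: int) -> np.ndarray:
    """Stratum label of each k-block.

    The block takes the stratum holding the plurality of its true
    population; blocks with no true population take the plurality of cell
    labels instead (so purely "halo" blocks are still evaluated under the
    stratum whose footprint they sit in). Ties break in the order
    slum > non-slum > rural.
    """
    order = (URBAN_SLUM, URBAN_NONSLUM, RURAL)  # argmax tie-break preference
    pop_by = np.stack([block_sum(np.where(strata == s, truth, 0.0), k) for s in order])
    area_by = np.stack([block_sum((strata == s).astype(np.float64), k) for s in order])
    pop_total = pop_by.sum(axis=0)
    scores = np.where(pop_total > 0, pop_by, area_by)
    winner = np.argmax(scores, axis=0)  # index into `order`
    return np.asarray(order, dtype=np.int8)[winner]


def stratify_and_report(
    est: np.ndarray,
    truth: np.ndarray,
    strata: np.ndarray,
    cfg: EvaluationConfig | None = None,
    scenario: str = "",
) -> pd.DataFrame:
    """All five statistics per (scale, stratum), plus an all-strata row.

    The inclusion threshold applies to the four error statistics at the
    evaluated scale; misallocated_pct deliberately uses every cell. Metric
    values that are undefined for a subgroup (zero true population under the
    mask, or zero estimated population for misallocation) are reported as
    NaN; subgroups with no included cells are omitted.
    """
    cfg = cfg or EvaluationConfig()
    est = np.asarray(est, dtype=np.float64)
    truth = np.asarray(truth, dtype=np.float64)
    rows = []
    for k in cfg.scales:
        est_k = aggregate_blocks(est, k)
        truth_k = aggregate_blocks(truth, k)
        strat_k = aggregate_strata(strata, truth, k)
        include = est_k >= cfg.inclusion_threshold
        groups = [("all", np.ones(est_k.shape, dtype=bool))]
        groups += [(name, strat_k == STRATUM_CODES[name]) for name in cfg.strata]
        for name, in_group in groups:
            sel = in_group & include
            n = int(sel.sum())
            if n > 0:
                t_mean = truth_k[sel].mean()
                rmse = float(np.sqrt(np.mean((est_k[sel] - truth_k[sel]) ** 2)))
                b = float(np.mean(est_k[sel] - truth_k[sel]))
                vals = {
                    "pop_adj_rmse": rmse / t_mean if t_mean > 0 else np.nan,
                    "density_rmse": rmse / k**2,
                    "bias": b,
                    "relative_bias": b / t_mean if t_mean > 0 else np.nan,
                }
                for metric, value in vals.items():
                    rows.append((scenario, 100 * k, name, metric, value, n))
            # misallocation: every cell of the group, no threshold
            n_group = int(in_group.sum())
            if n_group > 0:
                grp_total = est_k[in_group].sum()
                if grp_total > 0:
                    mis = 100.0 * est_k[in_group & (truth_k == 0)].sum() / grp_total
                else:
                    mis = np.nan
                rows.append((scenario, 100 * k, name, "misallocated_pct", mis, n_group))
    return pd.DataFrame(rows, columns=METRICS_COLUMNS)
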