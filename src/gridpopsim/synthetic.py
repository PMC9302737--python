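"""Synthetic "true" population generator.

Emulates a Khomas-like region: a dense city covering roughly 5% of an
otherwise almost unsettled grid, with urban-slum and urban-non-slum patches
inside the city and a sparse rural scatter outside it. Households are point
located, carry a construction year (so that filtering by year reproduces
configured historical counts), and a person count drawn from a truncated
discretised lognormal.

The module also generates the model inputs the downstream workflow needs:
synthetic covariate layers of mixed native resolution with tunable
informativeness about population density, and two nested areal-unit tilings
(enumeration-area-like small zones, constituency-like large zones).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml
from scipy import ndimage

from .grids import GridSpec, block_mean_expand

# stratum codes: ordered so that a larger code wins slum > non-slum > rural
# tie-breaks downstream.
RURAL, URBAN_NONSLUM, URBAN_SLUM = 0, 1, 2
STRATUM_NAMES = {RURAL: "rural", URBAN_NONSLUM: "urban_nonslum", URBAN_SLUM: "urban_slum"}
STRATUM_CODES = {v: k for k, v in STRATUM_NAMES.items()}
STRATA = ("urban_slum", "urban_nonslum", "rural")

HOUSEHOLD_COLUMNS = ["id", "x", "y", "stratum", "build_year", "persons"]

# Household counts per stratum and reference year. The urban columns follow
# the study's census-report-anchored trajectory verbatim; the rural 2011
# count is clamped to the 2016 value because the generative build-year model
# requires counts that never decrease over time (real building abandonment
# is out of scope).
DEFAULT_YEAR_COUNTS: dict[str, dict[int, int]] = {
    "urban_slum": {2001: 13_149, 2006: 18_018, 2011: 28_583, 2016: 35_001},
    "urban_nonslum": {2001: 41_700, 2006: 49_742, 2011: 55_680, 2016: 57_843},
    "rural": {2001: 3_731, 2006: 4_146, 2011: 4_823, 2016: 4_823},
}


def derive_rng(master_seed: int, *keys) -> np.random.Generator:
    """Independent substream keyed by operation name / scenario labels."""
    words = [int(master_seed) & 0x7FFFFFFF]
    words += [zlib.crc32(str(k).encode()) for k in keys]
    return np.random.default_rng(words)


@dataclass(frozen=True)
class CovariateSpec:
    """One synthetic ancillary layer.

    ``native_factor`` f makes the layer constant on f-by-f blocks, emulating
    covariates whose source resolution is coarser than the output grid (the
    "halo" mechanism). ``informativeness`` in [0, 1] scales the signal
    component (a monotone link of block-averaged log(1 + density));
    0 gives pure noise.
    """

    name: str
    native_factor: int = 1
    informativeness: float = 1.0
    noise_sd: float = 0.0

    def __post_init__(self):
        if self.native_factor < 1:
            raise ValueError("native_factor must be >= 1")
        if not 0.0 <= self.informativeness <= 1.0:
            raise ValueError("informativeness must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


DEFAULT_COVARIATES = (
    # one fine "distance-to-feature"-like layer: locates settlement but is a
    # weak predictor of density within it
    CovariateSpec("dist_builtup", native_factor=1, informativeness=0.3, noise_sd=0.5),
    # coarse ~900 m analogues (night-time lights, land cover, travel time)
    CovariateSpec("ntl", native_factor=9, informativeness=0.8, noise_sd=0.2),
    CovariateSpec("landcover_urban", native_factor=9, informativeness=0.6, noise_sd=0.3),
    CovariateSpec("travel_time", native_factor=9, informativeness=0.5, noise_sd=0.3),
)


@dataclass(frozen=True)
class SimulationConfig:
    """Full description of the synthetic world (YAML round-trippable)."""

    grid: GridSpec = field(default_factory=GridSpec)
    year_counts: dict = field(default_factory=lambda: {s: dict(c) for s, c in DEFAULT_YEAR_COUNTS.items()})
    years: tuple = (2001, 2006, 2011, 2016)
    mean_household_size: float = 4.0
    household_size_sigma: float = 0.5
    max_household_size: int = 15
    urban_fraction: float = 0.05     # city share of grid area
    n_slum_patches: int = 3
    slum_patch_radius: float = 12.0  # cells
    slum_decay: float = 6.0          # cells; household density e-folding in patches
    nonslum_decay: float = 30.0
    max_households_per_cell: int = 60
    n_small: int = 922
    n_large: int = 10
    covariates: tuple = DEFAULT_COVARIATES
    seed: int = 20160801

    @property
    def counts(self) -> dict[str, int]:
        """Current-year household counts per stratum."""
        return {s: int(yc[max(yc)]) for s, yc in self.year_counts.items()}

    def coarse_only(self) -> "SimulationConfig":
        """Restrict the covariate stack to its coarse (native_factor > 1) layers."""
        coarse = tuple(c for c in self.covariates if c.native_factor > 1)
        return replace(self, covariates=coarse)

    def validate(self) -> None:
        if self.n_small < self.n_large or self.n_large < 1:
            raise ValueError("need n_small >= n_large >= 1")
        for s in STRATA:
            if s not in self.year_counts:
                raise ValueError(f"year_counts missing stratum {s!r}")
            yc = self.year_counts[s]
            if any(v < 0 for v in yc.values()):
                raise ValueError("household counts must be >= 0")
            ordered = [yc[y] for y in sorted(yc)]
            if any(b < a for a, b in zip(ordered, ordered[1:])):
                raise ValueError(f"year_counts for {s!r} must be non-decreasing over years")

    # ---- YAML round trip -------------------------------------------------
    def to_dict(self) -> dict:
        d = {
            "grid": self.grid.to_dict(),
            "year_counts": {s: {int(y): int(n) for y, n in yc.items()} for s, yc in self.year_counts.items()},
            "years": list(self.years),
            "mean_household_size": self.mean_household_size,
            "household_size_sigma": self.household_size_sigma,
            "max_household_size": self.max_household_size,
            "urban_fraction": self.urban_fraction,
            "n_slum_patches": self.n_slum_patches,
            "slum_patch_radius": self.slum_patch_radius,
            "slum_decay": self.slum_decay,
            "nonslum_decay": self.nonslum_decay,
            "max_households_per_cell": self.max_households_per_cell,
            "n_small": self.n_small,
            "n_large": self.n_large,
            "covariates": [vars(c).copy() for c in self.covariates],
            "seed": self.seed,
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "grid" in d:
            d["grid"] = GridSpec.from_dict(d["grid"])
        if "covariates" in d:
            d["covariates"] = tuple(CovariateSpec(**c) for c in d["covariates"])
        if "years" in d:
            d["years"] = tuple(d["years"])
        if "year_counts" in d:
            d["year_counts"] = {s: {int(y): int(n) for y, n in yc.items()} for s, yc in d["year_counts"].items()}
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class CovariateStack:
    """Named per-cell layers sharing one grid."""

    names: list
    layers: np.ndarray  # (n_layers, n_rows, n_cols)
    specs: list

    def __getitem__(self, name: str) -> np.ndarray:
        return self.layers[self.names.index(name)]

    @property
    def n_layers(self) -> int:
        return len(self.names)


@dataclass
class ZoneMap:
    """Per-cell areal-unit labels, contiguous 1..K."""

    labels: np.ndarray  # int32, shape of grid
    level: str          # "small_zone" | "large_zone"

    @property
    def n_zones(self) -> int:
        return int(self.labels.max())


# ---------------------------------------------------------------------------
# household size distribution
# ---------------------------------------------------------------------------

def _lognormal_params(mean: float, sigma: float) -> tuple[float, float]:
    """(mu, sigma) of the underlying normal so the lognormal mean is ``mean``."""
    return float(np.log(mean) - 0.5 * sigma**2), float(sigma)


def household_size_pmf(config: SimulationConfig) -> tuple[np.ndarray, np.ndarray]:
    """Exact pmf of the integer household size.

    Sizes are a lognormal rounded to the nearest integer, floored at 1 and
    capped at ``max_household_size`` (probability mass of the tails collapses
    onto the bounds). Used by tests to get the distribution's moments without
    simulation.
    """
    from scipy.stats import lognorm

    mu, sigma = _lognormal_params(config.mean_household_size, config.household_size_sigma)
    dist = lognorm(s=sigma, scale=np.exp(mu))
    ks = np.arange(1, config.max_household_size + 1)
    upper = np.where(ks == config.max_household_size, np.inf, ks + 0.5)
    lower = np.where(ks == 1, 0.0, ks - 0.5)
    probs = dist.cdf(upper) - dist.cdf(lower)
    return ks, probs / probs.sum()


def _draw_household_sizes(n: int, config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    mu, sigma = _lognormal_params(config.mean_household_size, config.household_size_sigma)
    raw = rng.lognormal(mu, sigma, size=n)
    sizes = np.rint(raw).astype(np.int64)
    return np.clip(sizes, 1, config.max_household_size)


# ---------------------------------------------------------------------------
# stratum geography and household placement
# ---------------------------------------------------------------------------

def _stratum_geography(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Build the stratum label raster: slum patches inside an urban disk, rural
    everywhere else."""
    g = config.grid
    labels = np.full(g.shape, RURAL, dtype=np.int8)
    if config.urban_fraction <= 0:
        return labels

    r_urban = np.sqrt(config.urban_fraction * g.n_cells / np.pi)
    margin = r_urban + 2
    cy = rng.uniform(margin, g.n_rows - margin) if g.n_rows > 2 * margin else g.n_rows / 2
    cx = rng.uniform(margin, g.n_cols - margin) if g.n_cols > 2 * margin else g.n_cols / 2

    rr, cc = np.mgrid[0:g.n_rows, 0:g.n_cols]
    urban = (rr - cy) ** 2 + (cc - cx) ** 2 <= r_urban**2
    labels[urban] = URBAN_NONSLUM

    r_patch = config.slum_patch_radius
    max_off = max(r_urban - r_patch - 1, 0.0)
    for _ in range(config.n_slum_patches):
        theta = rng.uniform(0, 2 * np.pi)
        rho = np.sqrt(rng.uniform(0, 1)) * max_off
        py, px = cy + rho * np.sin(theta), cx + rho * np.cos(theta)
        patch = (rr - py) ** 2 + (cc - px) ** 2 <= r_patch**2
        labels[patch & urban] = URBAN_SLUM
    return labels


def _weighted_capped_allocation(
    weights: np.ndarray, n: int, cap: int, rng: np.random.Generator
) -> np.ndarray:
    """Sample ``n`` household-cell assignments with at most ``cap`` per cell.

    Each cell contributes ``cap`` slots carrying its weight; the ``n``
    winning slots are the top-n under exponential race sampling (weighted
    sampling without replacement).
    """
    cells = np.flatnonzero(weights > 0)
    if cells.size * cap < n:
        raise ValueError(
            f"capacity error: {cells.size} cells x cap {cap} cannot hold {n} households"
        )
    slot_cells = np.repeat(cells, cap)
    slot_w = np.repeat(weights[cells], cap)
    keys = rng.exponential(size=slot_cells.size) / slot_w
    winners = np.argpartition(keys, n - 1)[:n] if n < slot_cells.size else np.arange(slot_cells.size)
    return slot_cells[winners]


def simulate_households(
    config: SimulationConfig, seed: int | None = None
) -> tuple[pd.DataFrame, np.ndarray]:
    """Generate the current-year household table and the stratum raster.

    Returns
    -------
    households : DataFrame with columns id, x, y, stratum, build_year, persons
        ``build_year`` is initialised to the latest configured year; see
        :func:`assign_build_years` for the growth history.
    strata : int8 array of stratum codes per cell.
    """
    config.validate()
    if seed is None:
        seed = config.seed
    g = config.grid
    geo_rng = derive_rng(seed, "geography")
    strata = _stratum_geography(config, geo_rng)

    rr, cc = np.mgrid[0:g.n_rows, 0:g.n_cols]
    parts = []
    next_id = 0
    current_year = max(config.years)
    for name in STRATA:
        n = config.counts[name]
        if n == 0:
            continue
        code = STRATUM_CODES[name]
        mask = strata == code
        if not mask.any():
            raise ValueError(f"capacity error: no cells available for stratum {name!r}")
        rng = derive_rng(seed, "place", name)
        if code == RURAL:
            weights = mask.astype(float)
        else:
            # distance-decay from the interior of the settled patches: deep
            # cells are densest (edt = distance to the patch edge)
            depth = ndimage.distance_transform_edt(mask)
            decay = config.slum_decay if code == URBAN_SLUM else config.nonslum_decay
            weights = np.where(mask, np.exp(depth / decay), 0.0)
        cell_idx = _weighted_capped_allocation(
            weights.ravel(), n, config.max_households_per_cell, rng
        )
        row, col = np.unravel_index(cell_idx, g.shape)
        u = rng.uniform(0.0, 1.0, size=n)
        v = rng.uniform(0.0, 1.0, size=n)
        x = g.origin_x + (col + u) * g.cell_size
        y = g.origin_y - (row + v) * g.cell_size
        persons = _draw_household_sizes(n, config, rng)
        parts.append(
            pd.DataFrame(
                {
                    "id": np.arange(next_id, next_id + n, dtype=np.int64),
                    "x": x,
                    "y": y,
                    "stratum": name,
                    "build_year": current_year,
                    "persons": persons,
                }
            )
        )
        next_id += n
    if parts:
        households = pd.concat(parts, ignore_index=True)
    else:
        households = pd.DataFrame(
            {
                "id": pd.Series(dtype=np.int64),
                "x": pd.Series(dtype=float),
                "y": pd.Series(dtype=float),
                "stratum": pd.Series(dtype=object),
                "build_year": pd.Series(dtype=np.int64),
                "persons": pd.Series(dtype=np.int64),
            }
        )
    households = assign_build_years(households, config.year_counts, seed, grid=g, strata=strata)
    return households, strata


def assign_build_years(
    households: pd.DataFrame,
    year_counts: dict,
    seed: int,
    grid: GridSpec | None = None,
    strata: np.ndarray | None = None,
) -> pd.DataFrame:
    """Assign construction years so year-filtered counts match ``year_counts``.

    For each stratum and listed year Y, exactly ``year_counts[stratum][Y]``
    households receive ``build_year <= Y``. Interior households (far from the
    settlement fringe) are assigned the oldest years, emulating outward
    growth; a small random jitter breaks ties.

    Raises on year counts that decrease over time or whose final entry does
    not match the stratum's household count.
    """
    out = households.copy()
    if out.empty:
        return out
    fringe_depth = None
    if grid is not None and strata is not None:
        row, col = grid.cell_of(out["x"].to_numpy(), out["y"].to_numpy())
        settled = np.zeros(grid.shape, dtype=bool)
        settled[row, col] = True
        depth = ndimage.distance_transform_edt(settled)
        fringe_depth = depth[row, col]

    for name, group in out.groupby("stratum", sort=False):
        yc = year_counts[name]
        years = sorted(yc)
        counts = [int(yc[y]) for y in years]
        if any(b < a for a, b in zip(counts, counts[1:])):
            raise ValueError(f"year_counts for {name!r} must be non-decreasing over years")
        if counts[-1] != len(group):
            raise ValueError(
                f"final year count {counts[-1]} != {len(group)} households in stratum {name!r}"
            )
        rng = derive_rng(seed, "build_years", name)
        if fringe_depth is not None:
            score = fringe_depth[group.index.to_numpy()] + rng.normal(0, 0.75, size=len(group))
        else:
            score = rng.uniform(size=len(group))
        order = group.index.to_numpy()[np.argsort(-score, kind="stable")]  # interior first
        assigned = np.empty(len(group), dtype=np.int64)
        prev = 0
        for y, c in zip(years, counts):
            assigned[prev:c] = y
            prev = c
        out.loc[order, "build_year"] = assigned
    return out


# ---------------------------------------------------------------------------
# rasterisation
# ---------------------------------------------------------------------------

def rasterize(households: pd.DataFrame, grid: GridSpec) -> np.ndarray:
    """Per-cell person counts from household points (half-open cell rule)."""
    out = np.zeros(grid.shape, dtype=np.float64)
    if households.empty:
        return out
    try:
        row, col = grid.cell_of(households["x"].to_numpy(), households["y"].to_numpy())
    except ValueError:
        x, y = households["x"].to_numpy(), households["y"].to_numpy()
        bad = (
            (x < grid.origin_x)
            | (x >= grid.origin_x + grid.n_cols * grid.cell_size)
            | (y > grid.origin_y)
            | (y <= grid.origin_y - grid.n_rows * grid.cell_size)
        )
        ids = households["id"].to_numpy()[bad][:5].tolist()
        raise ValueError(f"household(s) outside grid extent: ids {ids}") from None
    np.add.at(out, (row, col), households["persons"].to_numpy().astype(np.float64))
    return out


# ---------------------------------------------------------------------------
# covariates
# ---------------------------------------------------------------------------

def synthesize_covariates(
    truth: np.ndarray, specs, seed: int
) -> CovariateStack:
    """Build ancillary layers from the true density surface.

    layer = informativeness * block_mean(log(1 + density)) + noise, with both
    the signal and the noise constant on native_factor blocks, so each layer
    is exactly block-constant at its native resolution.
    """
    specs = list(specs)
    if not specs:
        raise ValueError("need at least one covariate spec")
    base = np.log1p(np.asarray(truth, dtype=np.float64))
    n_rows, n_cols = base.shape
    layers = np.empty((len(specs), n_rows, n_cols))
    names = []
    for i, spec in enumerate(specs):
        rng = derive_rng(seed, "covariate", spec.name)
        f = spec.native_factor
        signal = block_mean_expand(base, f)
        if spec.noise_sd > 0:
            nb_r, nb_c = -(-n_rows // f), -(-n_cols // f)
            noise_blocks = rng.normal(0.0, spec.noise_sd, size=(nb_r, nb_c))
            noise = np.repeat(np.repeat(noise_blocks, f, axis=0), f, axis=1)[:n_rows, :n_cols]
        else:
            noise = 0.0
        layers[i] = spec.informativeness * signal + noise
        names.append(spec.name)
    return CovariateStack(names=names, layers=layers, specs=specs)


# ---------------------------------------------------------------------------
# zone delineation
# ---------------------------------------------------------------------------

def _morton_keys(rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
    """Z-order (Morton) keys by bit interleaving (16-bit coordinates)."""

    def spread(v: np.ndarray) -> np.ndarray:
        v = v.astype(np.uint64)
        v = (v | (v << 16)) & np.uint64(0x0000FFFF0000FFFF)
        v = (v | (v << 8)) & np.uint64(0x00FF00FF00FF00FF)
        v = (v | (v << 4)) & np.uint64(0x0F0F0F0F0F0F0F0F)
        v = (v | (v << 2)) & np.uint64(0x3333333333333333)
        v = (v | (v << 1)) & np.uint64(0x5555555555555555)
        return v

    return (spread(rows) << np.uint64(1)) | spread(cols)


def _balanced_cuts(weights: np.ndarray, n_parts: int) -> np.ndarray:
    """Partition an ordered weight sequence into ``n_parts`` consecutive runs
    of near-equal total weight; every run is non-empty. Returns part index
    (0-based) per element."""
    n = weights.size
    if n_parts > n:
        raise ValueError(f"cannot cut {n} elements into {n_parts} parts")
    cum = np.cumsum(weights, dtype=np.float64)
    total = cum[-1]
    part = np.zeros(n, dtype=np.int64)
    start = 0
    for k in range(1, n_parts):
        target = total * k / n_parts
        b = int(np.searchsorted(cum, target))
        b = max(b, start + 1)              # keep this run non-empty
        b = min(b, n - (n_parts - k))      # leave room for remaining runs
        part[b:] = k
        start = b
    return part


def delineate_zones(
    households: pd.DataFrame,
    grid: GridSpec,
    n_small: int,
    n_large: int,
    seed: int = 0,
) -> tuple[ZoneMap, ZoneMap]:
    """Two nested areal-unit tilings balanced on household counts.

    Settled cells are ordered along a Morton curve and cut into ``n_small``
    consecutive runs of near-equal household totals; every unsettled cell
    joins the zone of its nearest settled cell, so zones partition the grid.
    Large zones group consecutive small zones (again balanced), hence nest
    exactly. Deterministic given the household table; ``seed`` is accepted
    for interface symmetry.
    """
    if n_small < n_large or n_large < 1:
        raise ValueError("need n_small >= n_large >= 1")
    if households.empty:
        raise ValueError("need at least one household to delineate zones")
    row, col = grid.cell_of(households["x"].to_numpy(), households["y"].to_numpy())
    hh_counts = np.zeros(grid.shape, dtype=np.int64)
    np.add.at(hh_counts, (row, col), 1)
    settled_r, settled_c = np.nonzero(hh_counts)
    n_settled = settled_r.size
    if n_small > n_settled:
        raise ValueError(f"n_small={n_small} exceeds {n_settled} settled cells")

    order = np.argsort(_morton_keys(settled_r, settled_c), kind="stable")
    sr, sc = settled_r[order], settled_c[order]
    w = hh_counts[sr, sc].astype(np.float64)

    small_of_settled = _balanced_cuts(w, n_small) + 1  # labels 1..n_small

    small = np.zeros(grid.shape, dtype=np.int32)
    small[sr, sc] = small_of_settled
    # attach unsettled cells to the nearest settled cell's zone
    unsettled = hh_counts == 0
    if unsettled.any():
        _, (ir, ic) = ndimage.distance_transform_edt(unsettled, return_indices=True)
        small = small[ir, ic]

    zone_w = np.bincount(small_of_settled, weights=w, minlength=n_small + 1)[1:]
    large_of_small = _balanced_cuts(zone_w, n_large) + 1
    large = large_of_small[small - 1].astype(np.int32)

    return ZoneMap(labels=small, level="small_zone"), ZoneMap(labels=large, level="large_zone")


# ---------------------------------------------------------------------------
# household table I/O
# ---------------------------------------------------------------------------

def write_households(households: pd.DataFrame, path) -> None:
    households[HOUSEHOLD_COLUMNS].to_csv(path, index=False)


def read_households(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(HOUSEHOLD_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"household CSV missing columns {sorted(missing)}")
    return df[HOUSEHOLD_COLUMNS]
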