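"""Synthetic population generator: counts, growth history, covariates, zones."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import lognorm

from gridpopsim import (
    CovariateSpec,
    GridSpec,
    SimulationConfig,
    assign_build_years,
    delineate_zones,
    rasterize,
    simulate_households,
    synthesize_covariates,
)
from gridpopsim.synthetic import STRATUM_CODES, _lognormal_params


class TestSimulateHouseholds:
    def test_stratum_counts_match_config_exactly(self, small_world):
        config, households, strata = small_world
        counts = households.groupby("stratum").size().to_dict()
        assert counts == config.counts

    def test_households_sit_in_cells_of_their_stratum(self, small_world):
        config, households, strata = small_world
        row, col = config.grid.cell_of(households["x"].to_numpy(), households["y"].to_numpy())
        codes = households["stratum"].map(STRATUM_CODES).to_numpy()
        assert np.array_equal(strata[row, col], codes)

    def test_most_of_the_grid_is_unsettled(self, small_world):
        config, households, strata = small_world
        truth = rasterize(households, config.grid)
        assert (truth == 0).mean() > 0.8

    def test_slum_cells_denser_than_nonslum(self, small_world):
        config, households, strata = small_world
        truth = rasterize(households, config.grid)
        slum_mean = truth[(strata == 2) & (truth > 0)].mean()
        nonslum_mean = truth[(strata == 1) & (truth > 0)].mean()
        assert slum_mean > nonslum_mean

    def test_all_counts_zero_gives_empty_table_all_rural(self):
        cfg = SimulationConfig(
            grid=GridSpec(n_rows=30, n_cols=30),
            year_counts={s: {2016: 0} for s in ("urban_slum", "urban_nonslum", "rural")},
            urban_fraction=0.0,
            n_small=1,
            n_large=1,
        )
        households, strata = simulate_households(cfg, seed=0)
        assert households.empty
        assert (strata == STRATUM_CODES["rural"]).all()

    def test_mean_household_size_within_3_se_of_configured_distribution(self, small_world):
        """CLT oracle: the sample mean of persons-per-household must land
        within 3 standard errors of the exact truncated-lognormal mean,
        computed here by direct enumeration of the integer pmf."""
        config, households, _ = small_world
        mu, sigma = _lognormal_params(config.mean_household_size, config.household_size_sigma)
        dist = lognorm(s=sigma, scale=np.exp(mu))
        ks = np.arange(1, config.max_household_size + 1)
        upper = np.where(ks == config.max_household_size, np.inf, ks + 0.5)
        lower = np.where(ks == 1, 0.0, ks - 0.5)
        probs = dist.cdf(upper) - dist.cdf(lower)
        probs = probs / probs.sum()
        mean = (ks * probs).sum()
        sd = np.sqrt(((ks - mean) ** 2 * probs).sum())
        n = len(households)
        observed = households["persons"].sum() / n
        assert abs(observed - mean) <= 3 * sd / np.sqrt(n)

    def test_capacity_error_when_grid_too_small(self):
        cfg = SimulationConfig(
            grid=GridSpec(n_rows=10, n_cols=10),
            year_counts={
                "urban_slum": {2016: 50_000},
                "urban_nonslum": {2016: 0},
                "rural": {2016: 0},
            },
            n_small=1,
            n_large=1,
        )
        with pytest.raises(ValueError, match="capacity"):
            simulate_households(cfg, seed=0)

    def test_same_seed_is_bit_identical(self, small_config):
        a, sa = simulate_households(small_config, seed=5)
        b, sb = simulate_households(small_config, seed=5)
        pd.testing.assert_frame_equal(a, b)
        assert np.array_equal(sa, sb)


class TestBuildYears:
    def test_year_counts_reproduced_exactly(self, small_world):
        config, households, _ = small_world
        for stratum, yc in config.year_counts.items():
            sub = households[households["stratum"] == stratum]
            for year, expected in yc.items():
                assert (sub["build_year"] <= year).sum() == expected

    def test_year_filtering_is_monotone_subset_by_id(self, small_world):
        _, households, _ = small_world
        years = sorted(households["build_year"].unique())
        for y1, y2 in zip(years, years[1:]):
            ids1 = set(households.loc[households["build_year"] <= y1, "id"])
            ids2 = set(households.loc[households["build_year"] <= y2, "id"])
            assert ids1 <= ids2

    def test_constant_year_counts_mean_no_growth(self):
        hh = pd.DataFrame(
            {
                "id": range(4),
                "x": [50.0] * 4,
                "y": [-50.0] * 4,
                "stratum": ["rural"] * 4,
                "build_year": [2016] * 4,
                "persons": [3] * 4,
            }
        )
        out = assign_build_years(hh, {"rural": {2001: 4, 2006: 4, 2011: 4, 2016: 4}}, seed=0)
        assert (out["build_year"] == 2001).all()

    def test_decreasing_year_counts_rejected(self):
        hh = pd.DataFrame(
            {
                "id": [0, 1],
                "x": [50.0, 60.0],
                "y": [-50.0, -60.0],
                "stratum": ["rural", "rural"],
                "build_year": [2016, 2016],
                "persons": [2, 2],
            }
        )
        with pytest.raises(ValueError, match="non-decreasing"):
            assign_build_years(hh, {"rural": {2011: 2, 2016: 1}}, seed=0)

    def test_newer_households_sit_nearer_the_fringe(self, small_world):
        """Outward growth: urban households built in the earliest year should
        be deeper inside the settlement than the newest cohort."""
        config, households, strata = small_world
        from scipy import ndimage

        sub = households[households["stratum"] == "urban_slum"]
        row, col = config.grid.cell_of(sub["x"].to_numpy(), sub["y"].to_numpy())
        settled = np.zeros(config.grid.shape, dtype=bool)
        settled[row, col] = True
        depth = ndimage.distance_transform_edt(settled)[row, col]
        years = sub["build_year"].to_numpy()
        oldest, newest = years.min(), years.max()
        assert depth[years == oldest].mean() > depth[years == newest].mean()


class TestRasterize:
    def test_single_household_at_cell_centre(self):
        g = GridSpec(n_rows=4, n_cols=4)
        hh = pd.DataFrame(
            {"id": [0], "x": [150.0], "y": [-150.0], "stratum": ["rural"], "build_year": [2016], "persons": [5]}
        )
        out = rasterize(hh, g)
        assert out[1, 1] == 5
        assert out.sum() == 5

    def test_empty_table_gives_zero_raster(self):
        g = GridSpec(n_rows=3, n_cols=3)
        out = rasterize(pd.DataFrame(columns=["id", "x", "y", "stratum", "build_year", "persons"]), g)
        assert out.shape == (3, 3) and not out.any()

    def test_shared_edge_goes_to_half_open_owner(self):
        g = GridSpec(n_rows=4, n_cols=4)
        # x = x0 + s on the column-0/1 edge -> column 1
        hh = pd.DataFrame(
            {"id": [0], "x": [100.0], "y": [0.0], "stratum": ["rural"], "build_year": [2016], "persons": [2]}
        )
        out = rasterize(hh, g)
        assert out[0, 1] == 2 and out[0, 0] == 0

    def test_outside_extent_names_the_household(self):
        g = GridSpec(n_rows=2, n_cols=2)
        hh = pd.DataFrame(
            {"id": [7], "x": [10_000.0], "y": [0.0], "stratum": ["rural"], "build_year": [2016], "persons": [1]}
        )
        with pytest.raises(ValueError, match="7"):
            rasterize(hh, g)

    def test_raster_total_equals_total_persons(self, small_world):
        config, households, _ = small_world
        assert rasterize(households, config.grid).sum() == households["persons"].sum()


class TestCovariates:
    def test_perfect_covariate_equals_log1p_truth(self, small_world):
        config, households, _ = small_world
        truth = rasterize(households, config.grid)
        stack = synthesize_covariates(
            truth, [CovariateSpec("perfect", 1, 1.0, 0.0)], seed=3
        )
        assert np.allclose(stack["perfect"], np.log1p(truth))

    def test_coarse_layer_constant_on_9x9_blocks(self, small_world):
        config, households, _ = small_world
        truth = rasterize(households, config.grid)
        stack = synthesize_covariates(
            truth, [CovariateSpec("coarse", 9, 0.7, 0.4)], seed=3
        )
        layer = stack["coarse"]
        base = np.log1p(truth)
        for r0 in range(0, 120, 9):
            for c0 in range(0, 120, 9):
                blk = layer[r0 : r0 + 9, c0 : c0 + 9]
                assert np.allclose(blk, blk.flat[0])
                # the signal component matches the independently computed block mean
                noise = blk.flat[0] - 0.7 * base[r0 : r0 + 9, c0 : c0 + 9].mean()
                assert np.isfinite(noise)

    def test_zero_informativeness_is_uncorrelated_with_truth(self):
        rng = np.random.default_rng(9)
        truth = rng.poisson(3.0, size=(120, 120)).astype(float)  # >= 10^4 cells
        stack = synthesize_covariates(truth, [CovariateSpec("noise", 1, 0.0, 1.0)], seed=4)
        r = np.corrcoef(stack["noise"].ravel(), truth.ravel())[0, 1]
        assert abs(r) <= 0.05

    def test_empty_specs_rejected(self):
        with pytest.raises(ValueError, match="covariate"):
            synthesize_covariates(np.zeros((4, 4)), [], seed=0)


class TestZones:
    def test_single_zone_covers_everything(self, small_world):
        config, households, _ = small_world
        small, large = delineate_zones(households, config.grid, 1, 1)
        assert (small.labels == 1).all() and (large.labels == 1).all()

    def test_zone_counts_match_request(self, small_world):
        config, households, _ = small_world
        small, large = delineate_zones(households, config.grid, config.n_small, config.n_large)
        assert small.n_zones == config.n_small
        assert large.n_zones == config.n_large
        assert len(np.unique(small.labels)) == config.n_small
        assert len(np.unique(large.labels)) == config.n_large

    def test_partition_and_exact_nesting(self, small_world):
        config, households, _ = small_world
        small, large = delineate_zones(households, config.grid, config.n_small, config.n_large)
        assert small.labels.min() >= 1 and large.labels.min() >= 1
        # every small zone lies inside exactly one large zone
        for s in range(1, small.n_zones + 1):
            assert len(np.unique(large.labels[small.labels == s])) == 1

    def test_household_balance_ratio(self, small_world):
        config, households, _ = small_world
        small, _ = delineate_zones(households, config.grid, config.n_small, config.n_large)
        row, col = config.grid.cell_of(households["x"].to_numpy(), households["y"].to_numpy())
        counts = np.bincount(small.labels[row, col], minlength=small.n_zones + 1)[1:]
        occupied = counts[counts > 0]
        assert occupied.max() / occupied.min() <= 5

    def test_too_many_zones_rejected(self, small_world):
        config, households, _ = small_world
        with pytest.raises(ValueError, match="settled"):
            delineate_zones(households.head(3), config.grid, 10, 1)


class TestConfigIO:
    def test_yaml_roundtrip(self, tmp_path, small_config):
        path = tmp_path / "cfg.yaml"
        small_config.to_yaml(path)
        back = SimulationConfig.from_yaml(path)
        assert back == small_config

    def test_household_csv_roundtrip(self, tmp_path, small_world):
        from gridpopsim import read_households, write_households

        _, households, _ = small_world
        path = tmp_path / "hh.csv"
        write_households(households, path)
        back = read_households(path)
        assert len(back) == len(households)
        assert back["persons"].sum() == households["persons"].sum()
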