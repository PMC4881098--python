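"""Synthetic study generator: determinism, structure, and mortality."""

import numpy as np
import pandas as pd
import pytest

from topoepi import (
    SyntheticConfig,
    generate_dem,
    generate_mortality,
    generate_residential_mask,
    generate_study,
    generate_villages,
)
from topoepi.errors import ConfigError
from topoepi.synthetic import voronoi_villages
from topoepi.terrain import extract_rfa, focal_range
from tests.conftest import small_config


def basin_ring_masks(cfg: SyntheticConfig):
    """Cell masks for the basin interior and a surrounding ring."""
    r0, c0 = cfg.basin_center
    rr, cc = np.meshgrid(
        np.arange(cfg.grid_rows), np.arange(cfg.grid_cols), indexing="ij"
    )
    d = np.hypot(rr - r0, cc - c0)
    inner = d < 0.7 * cfg.basin_radius
    ring = (d >= cfg.basin_radius) & (d < 1.6 * cfg.basin_radius)
    return inner, ring


class TestDem:
    def test_degenerate_config_is_constant(self):
        cfg = small_config(
            roughness_sd_m=0.0, basin_depth_m=0.0, trend_slope_m=0.0
        )
        dem = generate_dem(cfg)
        assert np.all(dem.values == cfg.plateau_m)

    def test_basin_sits_below_its_ring(self):
        cfg = small_config(seed=1)
        dem = generate_dem(cfg)
        inner, ring = basin_ring_masks(cfg)
        assert dem.values[inner].mean() < dem.values[ring].mean()

    def test_deterministic_given_seed(self):
        cfg = small_config(seed=42)
        a, b = generate_dem(cfg), generate_dem(cfg)
        assert np.array_equal(a.values, b.values)

    def test_bad_dims_rejected(self):
        with pytest.raises(ConfigError):
            SyntheticConfig(grid_rows=0)

    def test_population_cap_enforced(self):
        with pytest.raises(ConfigError):
            SyntheticConfig(pop_range=(100, 40000))


class TestVillages:
    def test_corner_seeds_make_quadrants(self):
        seeds = np.array([[1.0, 1.0], [9.0, 1.0], [1.0, 9.0], [9.0, 9.0]])
        vs = voronoi_villages(seeds, (0.0, 0.0, 10.0, 10.0))
        assert len(vs) == 4
        for geom in vs.geometries:
            assert geom.area == pytest.approx(25.0)

    def test_tessellation_covers_grid(self):
        cfg = small_config()
        dem = generate_dem(cfg)
        vs = generate_villages(dem, cfg)
        total = sum(g.area for g in vs.geometries)
        grid_area = cfg.grid_rows * cfg.grid_cols * cfg.cell_size_m**2
        assert total == pytest.approx(grid_area, rel=1e-3)

    def test_polygons_do_not_overlap(self):
        cfg = small_config(n_villages=30)
        dem = generate_dem(cfg)
        vs = generate_villages(dem, cfg)
        for i in range(len(vs)):
            for j in range(i + 1, len(vs)):
                inter = vs.geometries[i].intersection(vs.geometries[j])
                assert inter.area == pytest.approx(0.0, abs=1e-6)

    def test_deterministic_given_seed(self):
        cfg = small_config(seed=9)
        dem = generate_dem(cfg)
        a = generate_villages(dem, cfg)
        b = generate_villages(dem, cfg)
        assert a.ids == b.ids
        assert all(x.equals(y) for x, y in zip(a.geometries, b.geometries))

    def test_too_many_villages_rejected(self):
        with pytest.raises(ConfigError):
            SyntheticConfig(grid_rows=10, grid_cols=10, n_villages=101)


class TestResidential:
    def test_flat_bias_concentrates_on_flat_cells(self):
        cfg = small_config(seed=1)
        dem = generate_dem(cfg)
        vs = generate_villages(dem, cfg)
        mask = generate_residential_mask(dem, vs, cfg)
        flat = extract_rfa(focal_range(dem))
        res = mask.values > 0.5
        flat_frac_res = flat[res].mean()
        flat_frac_all = flat.mean()
        assert flat_frac_res > flat_frac_all

    def test_every_village_has_a_residential_cell(self, small_study):
        assert (small_study.topography["VRA"] > 0).all()

    def test_unit_bias_places_independently_of_flatness(self):
        """With bias factor 1 the flat-cell count among residences
        matches the stratified (per-village) expectation over many
        seeds within Monte-Carlo error."""
        from topoepi.terrain import assign_cells_to_villages

        obs = exp = var = 0.0
        for seed in range(15):
            cfg = small_config(seed=seed, flat_bias=1.0)
            dem = generate_dem(cfg)
            vs = generate_villages(dem, cfg)
            flat = extract_rfa(focal_range(dem))
            mask = generate_residential_mask(dem, vs, cfg, flat_mask=flat)
            labels = assign_cells_to_villages(dem, vs)
            res = mask.values > 0.5
            obs += float((res & flat).sum())
            for k in range(len(vs)):
                member = labels == k
                n_res = int((res & member).sum())
                p_flat = flat[member].mean()
                exp += n_res * p_flat
                var += n_res * p_flat * (1 - p_flat)
        z = (obs - exp) / np.sqrt(var)
        assert abs(z) < 3.5

    def test_all_flat_dem_makes_bias_irrelevant(self):
        cfg = small_config(
            roughness_sd_m=0.0, basin_depth_m=0.0, trend_slope_m=0.0, seed=2
        )
        dem = generate_dem(cfg)
        vs = generate_villages(dem, cfg)
        rng_a = np.random.default_rng(7)
        rng_b = np.random.default_rng(7)
        biased = generate_residential_mask(dem, vs, cfg, rng=rng_a)
        unbiased_cfg = small_config(
            roughness_sd_m=0.0,
            basin_depth_m=0.0,
            trend_slope_m=0.0,
            seed=2,
            flat_bias=1.0,
        )
        unbiased = generate_residential_mask(dem, vs, unbiased_cfg, rng=rng_b)
        # every cell is flat, so the bias factor cancels out of the weights
        assert np.array_equal(biased.values, unbiased.values)


class TestMortality:
    def test_null_model_recovers_baseline_rate(self):
        """With no covariate effects the pooled crude rate matches the
        baseline within Monte-Carlo error."""
        cfg = small_config(
            beta_vdc=0.0,
            beta_rdls=0.0,
            noise_sd=0.0,
            n_periods=1,
            period_multipliers=None,
            pop_range=(10000, 19999),
            seed=3,
        )
        study = generate_study(cfg)
        m = study.mortality
        total_deaths = m["deaths"].sum()
        total_pop = m["population"].sum()
        pooled = 1e5 * total_deaths / total_pop
        se = 1e5 * np.sqrt(total_deaths) / total_pop
        assert abs(pooled - cfg.baseline_rate) < 3 * se

    def test_positive_vdc_slope_yields_positive_correlation(self):
        """Monte-Carlo sign check for the VDC effect on crude rates."""
        hits = 0
        n_seeds = 20
        for seed in range(n_seeds):
            cfg = small_config(
                beta_vdc=2.0, beta_rdls=0.0, noise_sd=0.0,
                pop_range=(15000, 25000), n_periods=1,
                period_multipliers=None, seed=seed,
            )
            study = generate_study(cfg)
            m = study.mortality
            rate = 1e5 * m["deaths"].to_numpy() / m["population"].to_numpy()
            vdc = study.topography["VDC"].to_numpy()
            if np.corrcoef(rate, vdc)[0, 1] > 0:
                hits += 1
        assert hits >= int(0.95 * n_seeds)

    def test_zero_population_flagged_excluded(self):
        cfg = small_config()
        study = generate_study(cfg)
        topo = study.topography
        rng = np.random.default_rng(0)
        pops = np.full(len(topo), 5000)
        pops[0] = 0
        mort, _ = generate_mortality(topo, cfg, rng=rng, populations=pops)
        first = mort[mort["village_id"] == topo.index[0]]
        assert (first["deaths"] == 0).all()
        assert first["excluded"].all()

    def test_truth_retained(self, small_study):
        truth = small_study.truth
        assert truth["beta_vdc"] == small_study.config.beta_vdc
        rates = truth["true_rates_per_1e5"]
        assert rates.shape == (
            len(small_study.topography),
            small_study.config.n_periods,
        )
        assert (rates.to_numpy() > 0).all()


class TestStudy:
    def test_bit_identical_given_seed(self):
        cfg = small_config(seed=21)
        a, b = generate_study(cfg), generate_study(cfg)
        assert np.array_equal(a.dem.values, b.dem.values)
        assert np.array_equal(a.residential.values, b.residential.values)
        assert a.villages.ids == b.villages.ids
        pd.testing.assert_frame_equal(a.mortality, b.mortality)
        pd.testing.assert_frame_equal(a.topography, b.topography)

    def test_different_seeds_differ(self):
        a = generate_study(small_config(seed=1))
        b = generate_study(small_config(seed=2))
        assert not np.array_equal(a.dem.values, b.dem.values)
        assert not a.mortality["deaths"].equals(b.mortality["deaths"])

    def test_deaths_do_not_exceed_population(self, default_study):
        m = default_study.mortality
        assert (m["deaths"] <= m["population"]).all()

    def test_basin_villages_flatter_than_ring(self, default_study):
        """Basin interior villages show lower relief and better dwelling
        conditions than ring villages."""
        cfg = default_study.config
        topo = default_study.topography
        cents = default_study.villages.subset(topo.index).centroids()
        x0, y0 = default_study.dem.origin
        col = (cents[:, 0] - x0) / cfg.cell_size_m
        row = (y0 - cents[:, 1]) / cfg.cell_size_m
        d = np.hypot(row - cfg.basin_center[0], col - cfg.basin_center[1])
        inner = d < 0.7 * cfg.basin_radius
        ring = (d >= cfg.basin_radius) & (d < 1.6 * cfg.basin_radius)
        assert inner.sum() >= 5 and ring.sum() >= 5
        assert topo.loc[inner, "RDLS"].mean() < topo.loc[ring, "RDLS"].mean()
        assert topo.loc[inner, "VDC"].mean() > topo.loc[ring, "VDC"].mean()
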