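"""Synthetic study generator: terrain, villages, residences, mortality.

The generator emulates the structure the analysis assumes in a
mountainous coal-burning region: a low "pocket-like" basin with a flat
floor ringed by higher, rougher terrain; irregular village polygons;
residential cells biased toward flat ground; and Poisson death counts
whose log-risk rises with the dwelling condition VDC and falls with the
relief index RDLS, on top of a spatially correlated noise field. The
true risk surface and slopes are retained so recovery can be tested.

All randomness is drawn from a single seeded NumPy generator; the stage
order is fixed (DEM, villages, residences, populations, log-risk noise,
deaths), so identical configurations reproduce bit-identical studies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from scipy import ndimage
from shapely import STRtree
from shapely.geometry import MultiPoint, box

from topoepi.config import SyntheticConfig
from topoepi.errors import ConfigError, DataError
from topoepi.grid import DEMGrid, ResidentialMask
from topoepi.terrain import (
    assign_cells_to_villages,
    extract_rfa,
    focal_range,
    zonal_topography,
)
from topoepi.villages import VillageSet

PER_1E5 = 1e5


@dataclass
class SyntheticStudy:
    """A complete generated study plus the truth used to generate it."""

    config: SyntheticConfig
    dem: DEMGrid
    villages: VillageSet
    residential: ResidentialMask
    flat_mask: np.ndarray
    topography: pd.DataFrame
    mortality: pd.DataFrame
    truth: dict


def _basin_profile(cfg: SyntheticConfig, rows: int, cols: int) -> np.ndarray:
    """Smooth bump in [0, 1]: 1 at the basin centre, 0 beyond its radius."""
    r0, c0 = cfg.basin_center
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    d = np.hypot(rr - r0, cc - c0)
    g = np.zeros((rows, cols))
    inside = d < cfg.basin_radius
    g[inside] = np.cos(0.5 * np.pi * d[inside] / cfg.basin_radius) ** 2
    return g


def _correlated_field(
    rng: np.random.Generator, rows: int, cols: int, corr_cells: float
) -> np.ndarray:
    """Unit-variance Gaussian random field with the given correlation length."""
    white = rng.standard_normal((rows, cols))
    if corr_cells <= 0:
        return white
    smooth = ndimage.gaussian_filter(white, sigma=corr_cells, mode="reflect")
    sd = smooth.std()
    return smooth / sd if sd > 0 else smooth


def generate_dem(
    cfg: SyntheticConfig, rng: np.random.Generator | None = None
) -> DEMGrid:
    """Generate the elevation raster: trend + basin bowl + correlated noise.

    The surface is a gentle regional ramp on a plateau, a bowl-shaped
    depression of ``basin_depth_m`` at ``basin_center``, and a
    correlated noise field whose amplitude is ``roughness_sd_m``
    outside the basin and damped by ``basin_smooth_factor`` inside it,
    giving the basin its flat floor.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    rows, cols = cfg.grid_rows, cfg.grid_cols
    rowfrac = np.arange(rows) / max(rows - 1, 1)
    trend = cfg.plateau_m + cfg.trend_slope_m * (0.5 - rowfrac)[:, None]
    trend = np.broadcast_to(trend, (rows, cols)).copy()
    bump = _basin_profile(cfg, rows, cols)
    bowl = -cfg.basin_depth_m * bump
    noise = _correlated_field(rng, rows, cols, cfg.roughness_corr_cells)
    amplitude = cfg.roughness_sd_m * (1.0 - (1.0 - cfg.basin_smooth_factor) * bump)
    values = np.maximum(trend + bowl + amplitude * noise, 0.0)
    return DEMGrid(
        values=values,
        cell_size_m=cfg.cell_size_m,
        origin=(0.0, rows * cfg.cell_size_m),
        crs_note="synthetic-projected-meters",
    )


def voronoi_villages(
    seeds: np.ndarray, bounds: tuple[float, float, float, float]
) -> VillageSet:
    """Voronoi tessellation of seed points clipped to a bounding box.

    ``seeds`` is an (n, 2) array of distinct (x, y) points inside
    ``bounds`` = (xmin, ymin, xmax, ymax). Village ids follow the seed
    order (``v0001`` ...), so the tessellation is deterministic.
    """
    seeds = np.asarray(seeds, dtype=float)
    if len(seeds) < 1:
        raise ConfigError("at least one seed point is required")
    frame = box(*bounds)
    cells = shapely.voronoi_polygons(MultiPoint(seeds.tolist()), extend_to=frame)
    polys = [p.intersection(frame) for p in cells.geoms]
    tree = STRtree(shapely.points(seeds[:, 0], seeds[:, 1]))
    ordered: list = [None] * len(seeds)
    for poly in polys:
        if poly.is_empty:
            continue
        hits = tree.query(poly, predicate="intersects")
        for h in hits:
            if ordered[h] is None:
                ordered[h] = poly
                break
    if any(p is None for p in ordered):
        raise DataError("Voronoi tessellation failed to cover every seed point")
    width = max(4, len(str(len(seeds))))
    ids = [f"v{k + 1:0{width}d}" for k in range(len(seeds))]
    return VillageSet(ids=ids, geometries=ordered, crs_note="synthetic-projected-meters")


def generate_villages(
    dem: DEMGrid, cfg: SyntheticConfig, rng: np.random.Generator | None = None
) -> VillageSet:
    """Tessellate the grid into villages via Voronoi of random cells.

    Seed points are the centres of ``n_villages`` distinct grid cells,
    which guarantees every village contains at least one cell centre.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    if cfg.n_villages < 4:
        raise ConfigError("n_villages must be at least 4")
    rows, cols = dem.shape
    if cfg.n_villages > rows * cols:
        raise ConfigError("n_villages exceeds the number of grid cells")
    flat_idx = rng.choice(rows * cols, size=cfg.n_villages, replace=False)
    xx, yy = dem.cell_centers()
    seeds = np.column_stack([xx.ravel()[flat_idx], yy.ravel()[flat_idx]])
    x0, y0 = dem.origin
    bounds = (x0, y0 - rows * dem.cell_size_m, x0 + cols * dem.cell_size_m, y0)
    return voronoi_villages(seeds, bounds)


def generate_residential_mask(
    dem: DEMGrid,
    villages: VillageSet,
    cfg: SyntheticConfig,
    rng: np.random.Generator | None = None,
    flat_mask: np.ndarray | None = None,
) -> ResidentialMask:
    """Place residential cells per village, biased toward flat ground.

    Within each village, between ``res_cells_range`` cells are sampled
    without replacement; a flat cell (3x3 range <= 30 m) carries
    ``flat_bias`` times the weight of a non-flat cell. Every village
    receives at least one residential cell.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    if flat_mask is None:
        flat_mask = extract_rfa(focal_range(dem))
    labels = assign_cells_to_villages(dem, villages)
    mask = np.zeros(dem.shape)
    flat_flat = flat_mask.ravel()
    labels_flat = labels.ravel()
    lo, hi = cfg.res_cells_range
    for k, vid in enumerate(villages.ids):
        candidates = np.flatnonzero(labels_flat == k)
        if candidates.size == 0:
            raise DataError(f"village {vid} has no candidate residential cells")
        n_res = min(int(rng.integers(lo, hi + 1)), candidates.size)
        n_res = max(n_res, 1)
        w = np.where(flat_flat[candidates], cfg.flat_bias, 1.0)
        chosen = rng.choice(candidates, size=n_res, replace=False, p=w / w.sum())
        mask.ravel()[chosen] = 1.0
    return DEMGrid(
        values=mask,
        cell_size_m=dem.cell_size_m,
        origin=dem.origin,
        nodata=-9999.0,
        crs_note=dem.crs_note,
    )


def generate_mortality(
    topo: pd.DataFrame,
    cfg: SyntheticConfig,
    rng: np.random.Generator | None = None,
    noise: np.ndarray | None = None,
    populations: np.ndarray | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Draw per-village, per-period populations and Poisson death counts.

    The per-person log risk is

        log(baseline/1e5) + beta_vdc * VDC + beta_rdls * RDLS + noise_i

    optionally scaled by a per-period multiplier. ``noise`` is a
    per-village field (spatially correlated when produced by
    :func:`generate_study`); if omitted it is drawn iid here.

    Returns the raw mortality table (village_id, period, deaths,
    population, excluded) and a truth dict holding the slopes and the
    true per-period rates per 100 000.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    n = len(topo)
    if populations is None:
        populations = rng.integers(cfg.pop_range[0], cfg.pop_range[1] + 1, size=n)
    populations = np.asarray(populations)
    if noise is None:
        noise = cfg.noise_sd * rng.standard_normal(n) if cfg.noise_sd > 0 else np.zeros(n)
    vdc = topo["VDC"].to_numpy(dtype=float)
    rdls = topo["RDLS"].to_numpy(dtype=float)
    usable = np.isfinite(vdc) & np.isfinite(rdls)
    log_risk = (
        np.log(cfg.baseline_rate / PER_1E5)
        + cfg.beta_vdc * np.where(usable, vdc, 0.0)
        + cfg.beta_rdls * np.where(usable, rdls, 0.0)
        + noise
    )
    base_rate = np.exp(log_risk)
    mults = (
        np.asarray(cfg.period_multipliers, dtype=float)
        if cfg.period_multipliers is not None
        else np.ones(cfg.n_periods)
    )
    records = []
    true_rates = {}
    for p in range(cfg.n_periods):
        rate_p = base_rate * mults[p]
        expected = populations * rate_p
        deaths = rng.poisson(expected)
        deaths = np.where(populations > 0, deaths, 0)
        true_rates[p] = rate_p * PER_1E5
        for i, vid in enumerate(topo.index):
            records.append(
                {
                    "village_id": vid,
                    "period": p,
                    "deaths": int(deaths[i]),
                    "population": int(populations[i]),
                    "excluded": bool(populations[i] == 0 or not usable[i]),
                }
            )
    mortality = pd.DataFrame.from_records(records)
    truth = {
        "beta_vdc": cfg.beta_vdc,
        "beta_rdls": cfg.beta_rdls,
        "baseline_rate": cfg.baseline_rate,
        "log_risk_noise": noise,
        "true_rates_per_1e5": pd.DataFrame(true_rates, index=topo.index),
    }
    return mortality, truth


def generate_study(cfg: SyntheticConfig) -> SyntheticStudy:
    """Run every generation stage in fixed order from one seeded generator."""
    rng = np.random.default_rng(cfg.seed)
    dem = generate_dem(cfg, rng)
    villages = generate_villages(dem, cfg, rng)
    flat_mask = extract_rfa(focal_range(dem))
    residential = generate_residential_mask(dem, villages, cfg, rng, flat_mask)
    topo = zonal_topography(dem, flat_mask, residential, villages)
    # spatially correlated log-risk noise, sampled at village centroid cells
    field = _correlated_field(rng, cfg.grid_rows, cfg.grid_cols, cfg.noise_corr_cells)
    centroids = villages.subset(topo.index).centroids()
    x0, y0 = dem.origin
    cc = np.clip(((centroids[:, 0] - x0) / dem.cell_size_m).astype(int), 0, cfg.grid_cols - 1)
    rr = np.clip(((y0 - centroids[:, 1]) / dem.cell_size_m).astype(int), 0, cfg.grid_rows - 1)
    noise = cfg.noise_sd * field[rr, cc]
    mortality, truth = generate_mortality(topo, cfg, rng, noise=noise)
    return SyntheticStudy(
        config=cfg,
        dem=dem,
        villages=villages,
        residential=residential,
        flat_mask=flat_mask,
        topography=topo,
        mortality=mortality,
        truth=truth,
    )
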