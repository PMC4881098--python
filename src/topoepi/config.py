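"""Configuration objects for the synthetic study and the analysis pipeline.

All tunables that the analysis depends on live here with their defaults:
the 3x3 focal window and the 30 m flatness threshold that define
relatively flat areas, the 500 m baseline-mountain constant of the RDLS
index, the contiguity rule, the reference mortality rate used for the
five-level categorisation, and the GWR kernel settings.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from topoepi.errors import ConfigError


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic study generator.

    The defaults describe a 12 km x 12 km mountainous grid (120x120
    cells of 100 m) holding one low basin ringed by higher, rougher
    terrain, 300 Voronoi villages, and mortality whose log-risk rises
    with VDC and falls with RDLS.

    Parameters
    ----------
    grid_rows, grid_cols : int
        Raster dimensions in cells.
    cell_size_m : float
        Cell edge length in meters (100 m, the DEM resolution the
        terrain indices were designed for).
    basin_center : (float, float)
        (row, col) of the basin centre in cell coordinates.
    basin_radius : float
        Basin radius in cells.
    basin_depth_m : float
        Depth of the bowl below the surrounding plateau, meters.
    plateau_m : float
        Elevation of the regional plateau trend, meters.
    trend_slope_m : float
        Total elevation gain of a gentle south-to-north regional ramp,
        meters (adds large-scale relief without affecting flatness).
    roughness_sd_m : float
        Standard deviation of the spatially correlated elevation noise
        outside the basin, meters.
    roughness_corr_cells : float
        Gaussian correlation length of the noise field, cells.
    basin_smooth_factor : float
        Multiplier applied to the noise amplitude inside the basin
        (valley floors are flatter than the surrounding ridges).
    n_villages : int
        Number of Voronoi villages.
    res_cells_range : (int, int)
        Min/max residential cells drawn per village.
    flat_bias : float
        Relative sampling weight of a flat cell (3x3 range <= 30 m)
        when placing residences; 1.0 means no bias.
    pop_range : (int, int)
        Uniform range of village populations (persons); max must stay
        below 30 000.
    baseline_rate : float
        Deaths per 100 000 person-periods when VDC = RDLS = 0.
    beta_vdc : float
        Log-risk slope per unit VDC (> 0 in the default study).
    beta_rdls : float
        Log-risk slope per unit RDLS (< 0 in the default study).
    noise_sd : float
        SD of the spatially correlated log-risk noise.
    noise_corr_cells : float
        Correlation length of the log-risk noise field, cells.
    n_periods : int
        Number of observation periods.
    period_multipliers : tuple of float or None
        Per-period multiplicative risk trend; None means all 1. Length
        must equal ``n_periods``.
    seed : int
        Seed for the single generator driving every random stage.
    """

    grid_rows: int = 120
    grid_cols: int = 120
    cell_size_m: float = 100.0
    basin_center: tuple[float, float] = (60.0, 60.0)
    basin_radius: float = 32.0
    basin_depth_m: float = 170.0
    plateau_m: float = 2192.0
    trend_slope_m: float = 120.0
    roughness_sd_m: float = 55.0
    roughness_corr_cells: float = 2.0
    basin_smooth_factor: float = 0.25
    n_villages: int = 300
    res_cells_range: tuple[int, int] = (2, 8)
    flat_bias: float = 4.0
    pop_range: tuple[int, int] = (500, 20000)
    baseline_rate: float = 300.0
    beta_vdc: float = 1.0
    beta_rdls: float = -0.6
    noise_sd: float = 0.15
    noise_corr_cells: float = 10.0
    n_periods: int = 3
    period_multipliers: tuple[float, ...] | None = (0.45, 0.90, 1.00)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grid_rows <= 0 or self.grid_cols <= 0:
            raise ConfigError("grid dimensions must be positive")
        if self.cell_size_m <= 0:
            raise ConfigError("cell_size_m must be positive")
        if self.n_villages <= 0:
            raise ConfigError("n_villages must be positive")
        if self.n_villages > self.grid_rows * self.grid_cols:
            raise ConfigError("n_villages exceeds the number of grid cells")
        if self.pop_range[0] < 0 or self.pop_range[1] < self.pop_range[0]:
            raise ConfigError("pop_range must be a non-negative (min, max) pair")
        if self.pop_range[1] >= 30000:
            raise ConfigError("village populations must stay below 30,000")
        if 2 * self.basin_radius * 1.0 >= min(self.grid_rows, self.grid_cols):
            raise ConfigError("basin diameter must fit inside the grid")
        if self.flat_bias <= 0:
            raise ConfigError("flat_bias must be positive")
        if self.baseline_rate <= 0:
            raise ConfigError("baseline_rate must be positive")
        if self.n_periods < 1:
            raise ConfigError("n_periods must be at least 1")
        if (
            self.period_multipliers is not None
            and len(self.period_multipliers) != self.n_periods
        ):
            raise ConfigError("period_multipliers length must equal n_periods")


@dataclass
class RateConfig:
    """Rate-processing parameters.

    Parameters
    ----------
    reference_rate : float
        R0, the reference (national rural age-standardised) mortality
        rate per 100 000 against which the five rate bands (below R0,
        1-2x, 2-3x, 3-4x, >= 4x) are cut.
    underreport_fraction : float
        Regional proportion of deaths missed by registration, in
        [0, 1); observed deaths are inflated by 1/(1 - fraction).
    """

    reference_rate: float = 30.0
    underreport_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.reference_rate <= 0:
            raise ConfigError("reference_rate must be positive")
        if not 0.0 <= self.underreport_fraction < 1.0:
            raise ConfigError("underreport_fraction must lie in [0, 1)")


@dataclass
class AnalysisConfig:
    """End-to-end pipeline configuration (paths + stage parameters)."""

    dem_path: str = ""
    villages_path: str = ""
    residential_path: str = ""
    mortality_path: str = ""
    output_dir: str = "topoepi_output"
    flat_threshold_m: float = 30.0
    focal_window: int = 3
    bm_m: float = 500.0
    contiguity_rule: str = "queen"
    eb_smoothing: bool = True
    reference_rate: float = 30.0
    underreport_fraction: float = 0.0
    permutations: int = 999
    seed: int = 0
    gwr_kernel: str = "adaptive_bisquare"
    gwr_bandwidth_bounds: tuple[float, float] | None = None
    synthetic: SyntheticConfig | None = None

    def __post_init__(self) -> None:
        if self.contiguity_rule not in ("queen", "rook"):
            raise ConfigError("contiguity_rule must be 'queen' or 'rook'")
        if self.focal_window < 3 or self.focal_window % 2 == 0:
            raise ConfigError("focal_window must be an odd integer >= 3")
        if self.flat_threshold_m < 0:
            raise ConfigError("flat_threshold_m must be non-negative")
        if self.bm_m <= 0:
            raise ConfigError("bm_m must be positive")

    def validate_paths(self) -> None:
        """Check that every input file exists before any stage runs."""
        for label, p in [
            ("dem_path", self.dem_path),
            ("villages_path", self.villages_path),
            ("residential_path", self.residential_path),
            ("mortality_path", self.mortality_path),
        ]:
            if not p:
                raise ConfigError(f"{label} is not set")
            if not Path(p).is_file():
                raise ConfigError(f"{label} does not exist: {p}")

    @property
    def rate_config(self) -> RateConfig:
        return RateConfig(
            reference_rate=self.reference_rate,
            underreport_fraction=self.underreport_fraction,
        )


def _coerce_tuples(cls, raw: dict) -> dict:
    """YAML gives lists; dataclass defaults use tuples for hashability."""
    out = {}
    fields = {f.name: f for f in dataclasses.fields(cls)}
    for key, value in raw.items():
        if key not in fields:
            raise ConfigError(f"unknown config key for {cls.__name__}: {key!r}")
        if isinstance(value, list):
            value = tuple(value)
        out[key] = value
    return out


def load_config(path: str | Path, kind: str = "analysis"):
    """Load a YAML config file into the requested config object.

    ``kind`` is ``"analysis"`` or ``"synthetic"``. An analysis file may
    embed a ``synthetic:`` section used by the ``simulate`` stage.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"config file {path} must contain a mapping")
    if kind == "synthetic":
        return SyntheticConfig(**_coerce_tuples(SyntheticConfig, raw))
    if kind == "analysis":
        sub = raw.pop("synthetic", None)
        cfg = AnalysisConfig(**_coerce_tuples(AnalysisConfig, raw))
        if sub is not None:
            cfg.synthetic = SyntheticConfig(**_coerce_tuples(SyntheticConfig, sub))
        return cfg
    raise ConfigError(f"unknown config kind: {kind!r}")
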