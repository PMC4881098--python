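"""End-to-end orchestration: simulate a study to disk, or run the
terrain → rates → clustering → association pipeline over input files.

Each stage writes plain-text artifacts (CSV, GeoJSON, ASCII grids)
into the configured output directory, plus a JSON run log holding the
configuration hash and seed so a run can be reproduced exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from topoepi.config import AnalysisConfig, SyntheticConfig
from topoepi.errors import ConfigError, DataError
from topoepi.grid import read_ascii_grid, write_ascii_grid
from topoepi.villages import (
    VillageSet,
    read_villages_geojson,
    write_villages_geojson,
)
from topoepi.terrain import extract_rfa, focal_range, zonal_topography
from topoepi.synthetic import generate_study
from topoepi.smoothing import (
    adjust_underreporting,
    categorize_rates,
    crude_rates,
    spatial_eb_smooth,
)
from topoepi.cluster import (
    build_contiguity_weights,
    classify_hotspots,
    gi_star,
    morans_i_inference,
    persistent_hotspots,
)
from topoepi.regression import (
    compare_models,
    pearson_correlation,
    stdresid_coverage,
)

logger = logging.getLogger(__name__)

ALL_STAGES = ("terrain", "rates", "cluster", "gwr")


def _config_hash(cfg) -> str:
    payload = json.dumps(dataclasses.asdict(cfg), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def simulate(cfg: SyntheticConfig, out_dir: str | Path) -> dict[str, str]:
    """Generate a synthetic study and write it in the pipeline's input
    formats (DEM and residential mask as ASCII grids, villages as
    GeoJSON, mortality as CSV). Returns the path of each artifact."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    study = generate_study(cfg)
    paths = {
        "dem": str(out / "dem.asc"),
        "residential": str(out / "residential.asc"),
        "villages": str(out / "villages.geojson"),
        "mortality": str(out / "mortality.csv"),
        "truth": str(out / "truth_rates.csv"),
    }
    write_ascii_grid(study.dem, paths["dem"])
    write_ascii_grid(study.residential, paths["residential"], fmt="%d")
    write_villages_geojson(study.villages, paths["villages"])
    study.mortality[["village_id", "period", "deaths", "population"]].to_csv(
        paths["mortality"], index=False
    )
    study.truth["true_rates_per_1e5"].to_csv(paths["truth"])
    logger.info("synthetic study written to %s", out)
    return paths


def _load_inputs(config: AnalysisConfig):
    config.validate_paths()
    dem = read_ascii_grid(config.dem_path)
    residential = read_ascii_grid(config.residential_path)
    villages = read_villages_geojson(config.villages_path)
    mortality = pd.read_csv(config.mortality_path, dtype={"village_id": str})
    if not residential.same_geometry(dem):
        raise DataError("residential raster is not aligned with the DEM")
    needed = {"village_id", "period", "deaths", "population"}
    if not needed.issubset(mortality.columns):
        raise DataError(f"mortality CSV must have columns {sorted(needed)}")
    return dem, residential, villages, mortality


def run_pipeline(
    config: AnalysisConfig, stages: tuple[str, ...] = ALL_STAGES
) -> dict:
    """Execute the analysis stages in order and write their outputs.

    Later stages always recompute the earlier results they depend on in
    memory; ``stages`` only controls which artifacts are written.
    Returns a dict with the in-memory tables.
    """
    unknown = set(stages) - set(ALL_STAGES)
    if unknown:
        raise ConfigError(f"unknown stages {sorted(unknown)}")
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    dem, residential, villages, mortality = _load_inputs(config)
    results: dict = {}

    # --- terrain ----------------------------------------------------
    logger.info("stage terrain: focal range, RFA mask, zonal indices")
    rng_raster = focal_range(dem, window=config.focal_window)
    flat = extract_rfa(rng_raster, threshold_m=config.flat_threshold_m)
    topo = zonal_topography(dem, flat, residential, villages, bm_m=config.bm_m)
    results["topography"] = topo
    if "terrain" in stages:
        topo.to_csv(out / "topography.csv")

    # --- rates ------------------------------------------------------
    logger.info("stage rates: crude, underreporting, EB smoothing, bands")
    mort = mortality[mortality["village_id"].isin(topo.index)].copy()
    if config.underreport_fraction > 0:
        mort["deaths"] = adjust_underreporting(
            mort["deaths"].to_numpy(), config.underreport_fraction
        )
    mort = crude_rates(mort)
    weights = build_contiguity_weights(
        villages.subset(topo.index), rule=config.contiguity_rule
    )
    if config.eb_smoothing:
        mort = spatial_eb_smooth(mort, weights)
    else:
        mort["smoothed_rate"] = mort["crude_rate"]
    mort["category"] = categorize_rates(
        mort["smoothed_rate"].to_numpy(), config.reference_rate
    )
    results["rates"] = mort
    results["weights"] = weights
    periods = sorted(mort["period"].unique())
    summary = _summary_table(mort, topo, periods)
    results["summary"] = summary
    if "rates" in stages:
        mort.to_csv(out / "mortality_rates.csv", index=False)
        summary.to_csv(out / "summary_table.csv", index=False)

    # --- cluster ----------------------------------------------------
    logger.info("stage cluster: Moran's I and Gi* hotspots")
    moran_rows = []
    gi_tables = []
    seed = config.seed
    rate_wide = mort.pivot_table(
        index="village_id", columns="period", values="smoothed_rate"
    ).reindex(topo.index)
    attributes = [(f"smoothed_rate_p{p}", rate_wide[p]) for p in periods]
    attributes += [("RDLS", topo["RDLS"]), ("VDC", topo["VDC"])]
    for k, (label, series) in enumerate(attributes):
        vals = series.to_numpy(dtype=float)
        keep = np.isfinite(vals)
        w_sub = weights.subset(list(series.index[keep]))
        res = morans_i_inference(
            vals[keep],
            w_sub,
            method="permutation",
            n_perm=config.permutations,
            seed=seed + k,
        )
        moran_rows.append(
            {
                "attribute": label,
                "morans_i": res.I,
                "z_score": res.z_score,
                "p_value": res.p_value,
                "method": res.method,
                "n": int(keep.sum()),
            }
        )
    moran_table = pd.DataFrame(moran_rows)
    results["moran"] = moran_table

    for p in periods:
        vals = rate_wide[p].to_numpy(dtype=float)
        keep = np.isfinite(vals)
        w_sub = weights.subset(list(rate_wide.index[keep]))
        gi = classify_hotspots(gi_star(vals[keep], w_sub))
        gi["period"] = p
        gi_tables.append(gi)
    results["hotspots"] = gi_tables
    shared = set.intersection(*[set(t.index) for t in gi_tables])
    aligned = [t.loc[sorted(shared)] for t in gi_tables]
    persistent = persistent_hotspots(aligned) if len(aligned) >= 2 else []
    results["persistent_hotspots"] = persistent
    if "cluster" in stages:
        moran_table.to_csv(out / "moran_table.csv", index=False)
        for p, gi in zip(periods, gi_tables):
            gi.to_csv(out / f"hotspots_period{p}.csv")
            props = {
                vid: {
                    "z": float(row["z"]),
                    "p": float(row["p_value"]),
                    "hotspot": row["hotspot"],
                }
                for vid, row in gi.iterrows()
            }
            write_villages_geojson(
                villages.subset(list(gi.index)),
                out / f"hotspots_period{p}.geojson",
                properties=props,
            )
        pd.DataFrame({"village_id": persistent}).to_csv(
            out / "persistent_hotspots.csv", index=False
        )

    # --- gwr / association -----------------------------------------
    logger.info("stage gwr: correlations and geographically weighted regression")
    corr_rows = []
    for p in periods:
        rate = rate_wide[p]
        for var in ("RDLS", "VDC"):
            try:
                cr = pearson_correlation(
                    rate.to_numpy(dtype=float),
                    topo[var].to_numpy(dtype=float),
                    label=f"smoothed_rate_p{p}~{var}",
                )
            except Exception:
                continue
            corr_rows.append(
                {"pair": cr.label, "r": cr.r, "p_value": cr.p_value, "n": cr.n}
            )
    cr = pearson_correlation(
        topo["RDLS"].to_numpy(dtype=float),
        topo["VDC"].to_numpy(dtype=float),
        label="RDLS~VDC",
    )
    corr_rows.append({"pair": cr.label, "r": cr.r, "p_value": cr.p_value, "n": cr.n})
    corr_table = pd.DataFrame(corr_rows)
    results["correlations"] = corr_table

    last = periods[-1]
    y_series = rate_wide[last]
    keep = (
        np.isfinite(y_series.to_numpy(dtype=float))
        & np.isfinite(topo["RDLS"].to_numpy(dtype=float))
        & np.isfinite(topo["VDC"].to_numpy(dtype=float))
    )
    ids_fit = list(topo.index[keep])
    coords = villages.subset(ids_fit).centroids()
    y_fit = y_series.loc[ids_fit].to_numpy(dtype=float)
    covs = topo.loc[ids_fit, ["RDLS", "VDC"]]
    comparison = compare_models(
        y_fit,
        covs,
        coords,
        kernel=config.gwr_kernel,
        bounds=config.gwr_bandwidth_bounds,
    )
    fits = comparison.attrs["fits"]
    comparison["stdresid_within2"] = [
        stdresid_coverage(fits[m]) for m in comparison["model"]
    ]
    best = comparison.iloc[0]["model"]
    best_fit = fits[best]
    best_local = best_fit.local.copy()
    best_local.insert(0, "village_id", ids_fit)
    results["model_comparison"] = comparison
    results["gwr_best"] = best_fit
    results["gwr_ids"] = ids_fit
    if "gwr" in stages:
        corr_table.to_csv(out / "correlation_table.csv", index=False)
        comparison.to_csv(out / "model_comparison.csv", index=False)
        best_local.to_csv(out / "gwr_local.csv", index=False)

    run_log = {
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "stages": list(stages),
        "n_villages": len(topo),
        "periods": [int(p) for p in periods],
        "best_model": best,
    }
    with open(out / "run_log.json", "w") as fh:
        json.dump(run_log, fh, indent=2)
    results["run_log"] = run_log
    return results


def _summary_table(
    mort: pd.DataFrame, topo: pd.DataFrame, periods
) -> pd.DataFrame:
    """Mean / range / SD of the smoothed rate per period and of the
    terrain indices — the study's descriptive summary layout."""
    rows = []
    for p in periods:
        vals = mort.loc[mort["period"] == p, "smoothed_rate"].dropna()
        rows.append(_describe(f"smoothed_rate_p{p}", vals))
    rows.append(_describe("RDLS", topo["RDLS"].dropna()))
    rows.append(_describe("VDC", topo["VDC"].dropna()))
    return pd.DataFrame(rows)


def _describe(label: str, vals: pd.Series) -> dict:
    arr = vals.to_numpy(dtype=float)
    return {
        "attribute": label,
        "n": len(arr),
        "mean": float(arr.mean()) if len(arr) else float("nan"),
        "range": float(np.ptp(arr)) if len(arr) else float("nan"),
        "sd": float(arr.std(ddof=1)) if len(arr) > 1 else float("nan"),
    }
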