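"""DEM-derived topographic indices at the village scale.

Two indices summarise how hospitable a village's terrain is:

* **VDC** (village dwelling condition): the fraction of a village's
  residential area lying in *relatively flat areas* (RFA) —

      VDC = VRA_f / VRA

  where VRA is the village residential area (km²) and VRA_f the part of
  it inside RFAs. An RFA cell is one whose 3x3-neighbourhood elevation
  range is at most 30 m.

* **RDLS** (relief degree of land surface): a composite of mean
  altitude, elevation range and the non-flat fraction of the village —

      RDLS = ALT/1000 + Range(H) * [1 - P(A)/A] / BM

  with ALT the mean altitude (m), Range(H) = max - min altitude (m),
  A the village area (km²), P(A) its flat area (km²), and BM = 500 m
  the baseline-mountain height used throughout mainland China.

All areas are raster areas: cell counts times the cell area, consistent
with the raster definition of flatness. Cells belong to the village
containing their centre; a centre on a shared boundary goes to the
first village in id order.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import shapely
from scipy import ndimage
from shapely import STRtree

from topoepi.errors import ConfigError, DataError
from topoepi.grid import DEMGrid, ResidentialMask
from topoepi.villages import VillageSet

logger = logging.getLogger(__name__)

DEFAULT_BM_M = 500.0
DEFAULT_FLAT_THRESHOLD_M = 30.0


def focal_range(dem: DEMGrid, window: int = 3) -> DEMGrid:
    """Per-cell elevation range (max - min) over a square moving window.

    The window shrinks at grid borders to the available cells, and
    nodata cells are excluded from it; a cell whose whole window is
    nodata gets nodata.

    Parameters
    ----------
    dem : DEMGrid
    window : odd int >= 3
        Window edge length in cells.

    Returns
    -------
    DEMGrid of ranges in meters, same geometry as ``dem``.
    """
    if window < 3 or window % 2 == 0:
        raise ConfigError(f"window must be an odd integer >= 3, got {window}")
    valid = dem.mask_valid
    hi = np.where(valid, dem.values, -np.inf)
    lo = np.where(valid, dem.values, np.inf)
    # constant +/-inf padding never wins max/min, so borders shrink
    fmax = ndimage.maximum_filter(hi, size=window, mode="constant", cval=-np.inf)
    fmin = ndimage.minimum_filter(lo, size=window, mode="constant", cval=np.inf)
    any_valid = (
        ndimage.uniform_filter(
            valid.astype(float), size=window, mode="constant", cval=0.0
        )
        > 1e-12
    )
    out = np.where(any_valid, fmax - fmin, dem.nodata)
    return DEMGrid(
        values=out,
        cell_size_m=dem.cell_size_m,
        origin=dem.origin,
        nodata=dem.nodata,
        crs_note=dem.crs_note,
    )


def extract_rfa(
    range_raster: DEMGrid, threshold_m: float = DEFAULT_FLAT_THRESHOLD_M
) -> np.ndarray:
    """Relatively-flat-area mask: range <= threshold (boundary inclusive).

    Nodata cells are never flat. Returns a boolean array aligned with
    the range raster.
    """
    if threshold_m < 0:
        raise ConfigError(f"threshold_m must be non-negative, got {threshold_m}")
    return range_raster.mask_valid & (range_raster.values <= threshold_m)


def assign_cells_to_villages(dem: DEMGrid, villages: VillageSet) -> np.ndarray:
    """Label each cell with the index of the village containing its centre.

    Returns an int array shaped like the grid; -1 marks cells in no
    village. A centre touched by several polygons (shared boundaries)
    is assigned to the first village in id order.
    """
    xx, yy = dem.cell_centers()
    points = shapely.points(xx.ravel(), yy.ravel())
    tree = STRtree(points)
    labels = np.full(xx.size, -1, dtype=int)
    # visiting villages in id order makes the first claim win ties
    order = sorted(range(len(villages)), key=lambda k: villages.ids[k])
    for k in order:
        hits = tree.query(villages.geometries[k], predicate="intersects")
        unclaimed = hits[labels[hits] == -1]
        labels[unclaimed] = k
    return labels.reshape(dem.shape)


def zonal_topography(
    dem: DEMGrid,
    flat_mask: np.ndarray,
    residential: ResidentialMask,
    villages: VillageSet,
    bm_m: float = DEFAULT_BM_M,
) -> pd.DataFrame:
    """Per-village zonal statistics and the VDC / RDLS indices.

    Parameters
    ----------
    dem : DEMGrid
    flat_mask : bool array
        RFA mask from :func:`extract_rfa`, aligned with ``dem``.
    residential : ResidentialMask
        0/1 raster aligned with ``dem``.
    villages : VillageSet
    bm_m : float
        Baseline-mountain height (m) of the RDLS formula.

    Returns
    -------
    DataFrame indexed by ``village_id`` with columns
    ``n_cells, ALT, RangeH, A, PA, VRA, VRA_f, VDC, vdc_defined, RDLS``.
    Villages containing no cell centre are dropped with a warning.
    """
    if flat_mask.shape != dem.shape:
        raise DataError("flat_mask is not aligned with the DEM")
    if not residential.same_geometry(dem):
        raise DataError("residential mask is not aligned with the DEM")

    labels = assign_cells_to_villages(dem, villages)
    valid = dem.mask_valid
    res = residential.values > 0.5
    cell_km2 = dem.cell_area_km2

    rows = []
    dropped = []
    for k, vid in enumerate(villages.ids):
        member = (labels == k) & valid
        n = int(member.sum())
        if n == 0:
            dropped.append(vid)
            continue
        elev = dem.values[member]
        alt = float(elev.mean())
        range_h = float(elev.max() - elev.min())
        a = n * cell_km2
        pa = int((member & flat_mask).sum()) * cell_km2
        vra = int((member & res).sum()) * cell_km2
        vra_f = int((member & res & flat_mask).sum()) * cell_km2
        vdc = compute_vdc(vra_f, vra)
        rows.append(
            {
                "village_id": vid,
                "n_cells": n,
                "ALT": alt,
                "RangeH": range_h,
                "A": a,
                "PA": pa,
                "VRA": vra,
                "VRA_f": vra_f,
                "VDC": vdc,
                "vdc_defined": bool(np.isfinite(vdc)),
                "RDLS": compute_rdls(alt, range_h, a, pa, bm_m=bm_m),
            }
        )
    if dropped:
        logger.warning(
            "excluded %d village(s) containing no cell centre: %s",
            len(dropped),
            ", ".join(dropped),
        )
    if not rows:
        raise DataError("no village contains any grid cell")
    return pd.DataFrame(rows).set_index("village_id")


def compute_vdc(vra_f: float, vra: float) -> float:
    """Dwelling condition VDC = VRA_f / VRA; NaN when VRA = 0."""
    vra_f = float(vra_f)
    vra = float(vra)
    if vra < 0 or vra_f < 0:
        raise DataError("residential areas must be non-negative")
    if vra_f > vra + 1e-12:
        raise DataError(f"VRA_f ({vra_f}) exceeds VRA ({vra})")
    if vra == 0:
        return float("nan")
    return vra_f / vra


def compute_rdls(
    alt: float, range_h: float, a: float, pa: float, bm_m: float = DEFAULT_BM_M
) -> float:
    """Relief degree of land surface.

    RDLS = ALT/1000 + Range(H) * [1 - P(A)/A] / BM, with ALT and
    Range(H) in meters and areas in km². The first term converts mean
    altitude to kilometers; the second scales the within-village relief
    by the non-flat area fraction and the baseline-mountain height.
    """
    if a <= 0:
        raise DataError(f"village area must be positive, got {a}")
    if pa < 0 or pa > a + 1e-12:
        raise DataError(f"flat area P(A)={pa} outside [0, A={a}]")
    if bm_m <= 0:
        raise ConfigError("bm_m must be positive")
    if range_h < 0:
        raise DataError("elevation range must be non-negative")
    return alt / 1000.0 + range_h * (1.0 - pa / a) / bm_m
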