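"""Compute the terrain indices (RFA, VDC, RDLS) on a tiny hand-made DEM.

A 6 x 6 grid holds a flat western half (1000 m) and a steep eastern
ramp (1100-1500 m), split into two villages. The flat village ends up
with VDC = 1 and RDLS = ALT/1000; the steep one with VDC = 0 and an
RDLS inflated by its 400 m relief.
"""

import numpy as np
from shapely.geometry import box

from topoepi import (
    DEMGrid,
    VillageSet,
    extract_rfa,
    focal_range,
    zonal_topography,
)

values = np.tile([1000.0, 1000.0, 1000.0, 1100.0, 1300.0, 1500.0], (6, 1))
dem = DEMGrid(values=values, cell_size_m=100.0, origin=(0.0, 600.0))

residential = np.zeros((6, 6))
residential[0, 0] = residential[0, 4] = residential[5, 5] = 1
res = DEMGrid(values=residential, cell_size_m=100.0, origin=(0.0, 600.0))

villages = VillageSet(
    ids=["flatland", "ridge"],
    geometries=[box(0, 0, 300, 600), box(300, 0, 600, 600)],
)

flat = extract_rfa(focal_range(dem), threshold_m=30.0)
topo = zonal_topography(dem, flat, res, villages)
print(topo[["ALT", "RangeH", "A", "PA", "VRA", "VRA_f", "VDC", "RDLS"]].round(3))

# flatland: every residential cell sits in flat terrain (VDC = 1.0) and
# RDLS = 1.0 (just its altitude in km). ridge: no flat cells at all, so
# VDC = 0 and RDLS = 1.3 + 400*(1-0)/500 = 2.1.
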