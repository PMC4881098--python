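# Methods

This note documents the models implemented in `topoepi`, the numerical and
design choices behind them, what the synthetic study generator does and does
not emulate, and the package's known limitations. Nothing here reports an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Terrain indices

**Relatively flat areas (RFA).** A DEM cell is flat when the elevation range
(max − min) over its 3×3 window is **≤ 30 m**, boundary inclusive. The focal
window shrinks at grid borders to the available cells, and nodata cells are
excluded from the window; a cell whose whole window is nodata stays nodata.
This matches the common GIS focal-statistics convention and avoids a nodata
halo along grid edges. Both the window size and the threshold are
configurable (`focal_window`, `flat_threshold_m`).

**VDC (village dwelling condition)** is the flat share of a village's
residential area, `VDC = VRA_f / VRA ∈ [0, 1]`. A village with no residential
area has an undefined VDC; it is retained with a `vdc_defined = False` flag
rather than dropped, so rate analyses that do not need VDC keep it.

**RDLS (relief degree of land surface)** combines mean altitude, elevation
range and the non-flat area fraction:

```
RDLS = ALT/1000 + Range(H) · [1 − P(A)/A] / BM ,   BM = 500 m
```

ALT and Range(H) in meters, areas in km². The first term is the altitude in
kilometers; the second scales within-village relief by the rough fraction of
the village and the baseline-mountain height BM, a constant conventionally
fixed at 500 m for mainland China (configurable). RDLS ≥ ALT/1000, with
equality exactly when the village has no relief or is entirely flat.

**Zonal statistics.** A cell belongs to the village polygon containing its
center; a center lying on a shared boundary goes to the first village in id
order (deterministic, standard zonal convention). All areas — A, P(A), VRA,
VRA_f — are *raster* areas (cell counts × cell area), consistent with the
raster definition of flatness; vector polygon areas are not mixed in.
Villages containing no cell center are excluded with a warning naming them.

## Rate processing

Rates are carried per 100 000 throughout. Underreporting is corrected by
inflating observed deaths to `deaths / (1 − fraction)` with a per-region
fraction in [0, 1). Villages with zero population are flagged excluded.

**Spatial empirical Bayes smoothing** shrinks each village's crude rate
toward the pooled rate of its contiguity neighbourhood J = N(i) ∪ {i}
(the village's own experience is part of its reference — the defining
feature of the *locally varying* reference mean). With pooled deaths D_J,
population P_J, k = |J| and per-person rates r_j:

```
m_i  = D_J / P_J
s²_i = Σ_J p_j (r_j − m_i)² / P_J − m_i / (P_J / k)      floored at 0
w_i  = s²_i / (s²_i + m_i / p_i)
EB_i = w_i r_i + (1 − w_i) m_i
```

A negative moment estimate of the prior variance floors at 0, giving w = 0
and full shrinkage to the local mean. The formulas are evaluated on the
per-person scale — where the Poisson sampling variance of a rate is m/p, so
the shrinkage weight is scale-consistent — and converted to per-100 000 only
for reporting. An isolated village is smoothed against itself alone (w = 0,
EB = crude) with a warning. The estimator is a convex combination, so every
smoothed rate lies between the crude rate and the local mean; shrinkage
decreases monotonically with population.

**Five-level bands** cut the smoothed rate at multiples of a reference rate
R0 (the national rural age-standardized rate for the disease): band 1 below
R0, bands 2–4 the 1–2×, 2–3×, 3–4× intervals (lower bound inclusive), band 5
at or above 4×R0. R0 is a required configuration scalar (default 30 per
100 000, a typical rural lung-cancer figure); the package does not perform
age standardization itself.

## Spatial clustering

**Weights** are binary polygon contiguity: queen (any shared boundary point)
by default — the usual choice for irregular administrative polygons — with
rook (shared segment of positive length) selectable. The matrix is
deliberately **not row-standardized**, because the Moran's I and Gi*
formulas below are defined on the raw 0/1 weights. Islands are allowed with
a warning.

**Moran's I** is evaluated exactly as

```
I = N Σ_i Σ_j ω_ij (x_i − x̄)(x_j − x̄) / [(Σ_i Σ_j ω_ij) Σ_i (x_i − x̄)²]
```

Inference defaults to a random-permutation test (999 draws, seeded): the
attribute is shuffled over the villages, the tail count in the direction of
the observed deviation carries the +1 correction
`(1 + #extreme) / (n_perm + 1)` — so p is never exactly 0 — and is doubled
(capped at 1) for the default two-sided alternative, which keeps the test's
size at the nominal level under iid data. The pseudo z-score is
(I − mean)/sd of the permutation distribution. The analytic
randomization-moments normal approximation is available as `method=
"analytic"` for parity with software that prints moment-based Z scores.

**Getis-Ord Gi\*** is computed per village as

```
Gi* = [Σ_j ω_ij x_j − X̄ Σ_j ω_ij] / (S √([n Σ_j ω²_ij − (Σ_j ω_ij)²]/(n−1)))
X̄ = Σ_j x_j / n ,  S = √(Σ_j x²_j / n − X̄²)
```

with the focal village always included in its own neighbourhood — the
defining difference between Gi* and the plain Gi statistic. Gi* is already a
z-score; classes use the two-sided normal thresholds |z| ≥ 1.960 (95%) and
|z| ≥ 2.576 (99%), sign giving hot vs cold. No multiple-testing correction
is applied by default (each village's class is a descriptive label, not a
family-wise inference). A village connected to every other village has a
zero Gi* denominator; this is reported as an undefined-statistic error.
**Persistent hotspots** are villages classed hot (≥ 95%) in *every* period
of a multi-period study.

## Association

Pearson correlations use the exact t-test p-value; the conventional
significance level in this literature is 0.01.

**GWR.** At each village location a weighted least-squares fit is computed
with kernel weights over inter-centroid distance. Kernels:

- *adaptive bisquare* (default): bandwidth is a neighbour count k; the
  kernel radius at location i is the distance to its k-th nearest village,
  so sparse areas get wide kernels. Robust to irregular village density.
- *fixed Gaussian*: bandwidth is a distance; weights never vanish.

An infinite bandwidth gives uniform weights and reduces every local fit to
the global OLS solution (verified to 1e-8). Covariates are z-standardized
before fitting to stabilize the bandwidth search; reported coefficients are
back-transformed to the raw scale, so standardization is invisible to the
user. The hat-matrix diagonal gives the effective number of parameters
tr(S); fit quality is summarized by global R², adjusted R² (using n − tr(S)
denominator, which reduces to the classical formula at OLS), and the
small-sample corrected criterion

```
AICc = 2n ln σ̂ + n ln 2π + n (n + tr(S)) / (n − 2 − tr(S)) ,  σ̂² = RSS/n
```

Bandwidth is selected by golden-section search on AICc (integer-rounded for
the adaptive kernel, default bounds [2(p+1)+2, n]); the search is
deterministic, so repeated runs select identical bandwidths. Standardized
residuals are `e_i / (σ̂ √(1 − S_ii))` with σ̂² = RSS/(n − tr(S)); a
numerically exact fit reports zero residuals rather than noise ratios.
`compare_models` fits the RDLS-only, VDC-only and combined variants on
identical observations and ranks them by AICc; `stdresid_coverage` reports
the fraction of villages with standardized residual in [−2, 2], the
conventional band for an adequate local fit.

## Synthetic study generator

The generator reproduces the *structure* the analysis assumes, not any real
geography. Stages run in fixed order (DEM → villages → residences →
populations → log-risk noise → deaths) from one seeded NumPy generator, so
identical configurations give bit-identical studies.

- **DEM** (default 120×120 cells of 100 m): a plateau at 2192 m with a
  gentle 120 m north–south ramp, a cosine-profile bowl 170 m deep and 32
  cells in radius at the center, plus a correlated Gaussian noise field
  (55 m SD, 2-cell correlation length) whose amplitude is damped to 25%
  inside the bowl. The damping is what makes the basin floor *flat* as well
  as low, so basin villages get lower RDLS and higher VDC than ring
  villages — the structural contract the clustering and association stages
  rely on. The plateau/depth values are calibrated loosely to a basin floor
  near 2020 m inside a ring near 2190 m.
- **Villages** (default 300): Voronoi cells of 300 distinct random grid-cell
  centers, clipped to the grid. Snapping seeds to cell centers guarantees
  every village contains at least one cell, so no village is lost to zonal
  statistics. Ids are stable (`v0001`…) in seed order.
- **Residences**: 2–8 cells per village, sampled without replacement with
  flat cells carrying 4× the weight of rough cells (people settle the flat
  pockets); at least one cell per village.
- **Mortality**: populations uniform on [500, 20 000] (kept below the
  30 000 ceiling that motivates small-area smoothing); per-person log risk
  `log(300/10⁵) + 1.0·VDC − 0.6·RDLS + ε` with ε a spatially correlated
  field (SD 0.15, 10-cell correlation length) sampled at village centroids;
  deaths Poisson with per-period multipliers (0.45, 0.90, 1.00) emulating a
  rising epidemic over three periods. With the default terrain this lands
  the mean rate near 50 / 95 / 105 per 100 000 across the periods and mean
  VDC near 0.4. The true rate surface and slopes are retained in
  `SyntheticStudy.truth`.

What the generator does **not** emulate: age structure (rates are
all-ages), real administrative boundaries, migration, multi-basin terrain,
wind or pollution transport, and reporting artifacts other than a uniform
underreporting fraction. Passing tests therefore demonstrate that the
estimators recover known structure of this idealized class — smooth risk
surfaces over contiguous polygons — not that any particular real dataset
would behave the same way.

## Problem sizes and runtime choices

The test and acceptance workloads use the study's own default scale
(300 villages on a 120×120 grid, three periods) for end-to-end checks, a
60×60/80-village configuration for fast unit tests, Monte-Carlo ensembles of
50 seeds for sign-recovery and smoothing-RMSE checks, 100 seeds for GWR
model selection, and 500 replicates (999 permutations each, 200 villages)
for the permutation-test calibration. These sizes give stable Monte-Carlo
estimates at interactive runtimes.

## Known limitations

- CRS handling is intentionally minimal: all inputs must share one projected
  CRS in meters (carried as an identifier string); no reprojection is done,
  mismatched inputs are an error.
- Rasters are read/written as ESRI ASCII grids only.
- The Gi* p-values are plain normal tail areas; with hundreds of villages
  some 95% flags are expected by chance (an optional FDR adjustment is out
  of scope of the default output).
- GWR standard errors for individual local coefficients are not reported;
  diagnostics are residual-based.
- The EB prior-variance estimator can floor at zero in very homogeneous
  neighbourhoods, collapsing to the local mean; this is the standard
  behaviour of the moment estimator, not a fitting failure.
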