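# topoepi

Village-scale spatial epidemiology of mortality versus terrain.

In mountainous coal-burning regions, low basins ringed by higher ground can
trap air pollution, and people preferentially settle on the scarce flat land
inside them. `topoepi` implements the full analysis chain used to ask whether
small-area (village) mortality tracks such topography:

1. **Terrain indices** from a DEM (100 m cells):
   *relatively flat areas* (RFA: cells whose 3×3-window elevation range is
   ≤ 30 m), the **village dwelling condition**

   `VDC = VRA_f / VRA`

   (the fraction of a village's residential area lying in flat terrain), and
   the **relief degree of land surface**

   `RDLS = ALT/1000 + Range(H) · [1 − P(A)/A] / BM`

   with ALT the mean altitude (m), Range(H) the max−min altitude (m), A the
   village area, P(A) its flat area (km²), and BM = 500 m the
   baseline-mountain height.
2. **Rates**: crude mortality per 100 000, underreporting adjustment
   (deaths / (1 − fraction)), **spatial empirical Bayes smoothing** toward a
   locally varying neighbourhood reference mean, and five rate bands relative
   to a reference rate R0 (below R0, 1–2×, 2–3×, 3–4×, ≥ 4×).
3. **Clustering**: binary queen/rook contiguity weights, global **Moran's I**
   with permutation or analytic inference, local **Getis-Ord Gi\*** z-scores
   with 95%/99% hot/cold classes, and **persistent hotspots** (hot in every
   period).
4. **Association**: Pearson correlations and **geographically weighted
   regression** (adaptive bisquare or fixed Gaussian kernel, AICc-selected
   bandwidth), comparing RDLS-only, VDC-only and combined models, with
   standardized-residual diagnostics.

Because real survey mortality and cadastral layers of this kind are not
publicly deposited, the package ships a first-class **synthetic study
generator** (`topoepi.synthetic`): a basin-and-ring DEM, Voronoi villages,
flat-biased residences and Poisson deaths whose log-risk rises with VDC and
falls with RDLS, with the generating truth retained for recovery tests.

## Worked example

```python
from topoepi import SyntheticConfig, generate_study, build_contiguity_weights, \
    crude_rates, spatial_eb_smooth, morans_i_inference

study = generate_study(SyntheticConfig(seed=7))
weights = build_contiguity_weights(study.villages.subset(study.topography.index))
mort = spatial_eb_smooth(crude_rates(study.mortality), weights)
sub = mort[mort["period"] == 2].set_index("village_id")
res = morans_i_inference(sub["smoothed_rate"].to_numpy(), weights,
                         n_perm=999, seed=2)
print(f"Moran's I = {res.I:+.3f}, z = {res.z_score:.1f}, p = {res.p_value:.3f}")
```

prints

```
Moran's I = +0.396, z = 11.7, p = 0.002
```

— the smoothed rate is strongly spatially clustered (I > 0, permutation
p at the resolution floor of 999 permutations). The scripts in `examples/`
walk through each capability the same way; `examples/05_gwr.py` ends with

```
   model     aicc    r2  adj_r2  bandwidth
     VDC 2778.642 0.762   0.695       23.0
RDLS+VDC 2799.087 0.704   0.642       41.0
    RDLS 2886.697 0.625   0.536       25.0
best model: VDC, std residuals within [-2, 2]: 93.7%
```

the VDC-only model explaining the rate surface best by AICc, with ~94% of
standardized residuals inside [−2, 2] — a locally stable fit.

## Command line

```bash
topoepi simulate --config examples/config.yaml --out simdir
topoepi run-all  --config examples/config.yaml
```

Subcommands `terrain`, `rates`, `cluster`, `gwr` write the corresponding
stage outputs; exit codes distinguish configuration (2), data (3) and
numerical (4) errors.

## Layout

- `src/topoepi/` — `terrain`, `smoothing`, `cluster`, `regression`,
  `synthetic`, `pipeline`, `cli`, plus raster/vector I/O.
- `examples/` — one short narrative script per capability.
- `docs/methods.md` — models, assumptions, parameter choices, limitations.
- `tests/` — unit, property and end-to-end suites with independent
  brute-force/hand oracles.
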