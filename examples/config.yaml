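# Example pipeline configuration for the topoepi CLI.
#
#   topoepi simulate --config examples/config.yaml --out simdir
#   # point the four input paths at simdir/... , then:
#   topoepi run-all --config examples/config.yaml

dem_path: simdir/dem.asc
villages_path: simdir/villages.geojson
residential_path: simdir/residential.asc
mortality_path: simdir/mortality.csv
output_dir: topoepi_output

flat_threshold_m: 30.0   # RFA rule: 3x3 elevation range at or below this
focal_window: 3
bm_m: 500.0              # baseline-mountain height in the RDLS formula
contiguity_rule: queen
eb_smoothing: true
reference_rate: 30.0     # R0 per 100,000 for the five-level bands
underreport_fraction: 0.0
permutations: 999
seed: 1
gwr_kernel: adaptive_bisquare

synthetic:
  n_villages: 300
  seed: 1
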