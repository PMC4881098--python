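"""Global and local spatial clustering of the smoothed mortality rate.

Moran's I asks whether similar rates cluster anywhere on the map;
Gi* asks where. Persistent hotspots are villages hot in every period —
the analogue of a stable high-risk core inside a pollution-trapping
basin.
"""

from topoepi import (
    SyntheticConfig,
    build_contiguity_weights,
    classify_hotspots,
    crude_rates,
    generate_study,
    gi_star,
    morans_i_inference,
    persistent_hotspots,
    spatial_eb_smooth,
)

study = generate_study(SyntheticConfig(seed=7))
topo = study.topography
weights = build_contiguity_weights(study.villages.subset(topo.index))
mort = spatial_eb_smooth(crude_rates(study.mortality), weights)

tables = []
for period in sorted(mort["period"].unique()):
    sub = mort[mort["period"] == period].set_index("village_id").loc[topo.index]
    x = sub["smoothed_rate"].to_numpy()
    res = morans_i_inference(x, weights, n_perm=999, seed=int(period))
    print(
        f"period {period}: Moran's I = {res.I:+.3f}, "
        f"z = {res.z_score:.1f}, p = {res.p_value:.3f}"
    )
    tables.append(classify_hotspots(gi_star(x, weights)))

persistent = persistent_hotspots(tables)
print(f"persistent hotspot villages (hot in all periods): {len(persistent)}")

# Positive, highly significant Moran's I in every period says rates are
# spatially clustered; the persistent set marks the stable core of the
# hotspot region.
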