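"""Spatial weights, Moran's I, Gi* and hotspot classification."""

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import box

from topoepi import (
    SpatialWeights,
    VillageSet,
    build_contiguity_weights,
    classify_hotspots,
    gi_star,
    morans_i,
    morans_i_inference,
    persistent_hotspots,
)
from topoepi.errors import ConfigError, DataError, NumericalError
from tests.conftest import random_voronoi


def brute_force_morans_i(x, w):
    """Literal double-sum evaluation of the Moran's I formula."""
    x = np.asarray(x, float)
    n = len(x)
    xbar = x.mean()
    num = 0.0
    s0 = 0.0
    for i in range(n):
        for j in range(n):
            num += w[i, j] * (x[i] - xbar) * (x[j] - xbar)
            s0 += w[i, j]
    return n * num / (s0 * sum((xi - xbar) ** 2 for xi in x))


def brute_force_gi_star(x, w_with_self):
    """Literal per-village evaluation of the Gi* z-score."""
    x = np.asarray(x, float)
    n = len(x)
    xbar = sum(x) / n
    s = np.sqrt(sum(v**2 for v in x) / n - xbar**2)
    out = []
    for i in range(n):
        wsum = sum(w_with_self[i, j] for j in range(n))
        wsq = sum(w_with_self[i, j] ** 2 for j in range(n))
        num = sum(w_with_self[i, j] * x[j] for j in range(n)) - xbar * wsum
        den = s * np.sqrt((n * wsq - wsum**2) / (n - 1))
        out.append(num / den)
    return np.array(out)


def square_lattice_villages(rows, cols, size=100.0):
    ids, geoms = [], []
    for r in range(rows):
        for c in range(cols):
            ids.append(f"r{r}c{c}")
            geoms.append(box(c * size, -r * size, (c + 1) * size, -(r - 1) * size))
    return VillageSet(ids=ids, geometries=geoms)


class TestContiguityWeights:
    def test_2x2_rook_has_two_neighbors_each(self):
        vs = square_lattice_villages(2, 2)
        w = build_contiguity_weights(vs, rule="rook")
        assert (w.n_neighbors == 2).all()

    def test_2x2_queen_has_three_neighbors_each(self):
        vs = square_lattice_villages(2, 2)
        w = build_contiguity_weights(vs, rule="queen")
        assert (w.n_neighbors == 3).all()

    def test_voronoi_matches_brute_force_touch_test(self):
        rng = np.random.default_rng(4)
        vs = random_voronoi(rng, 25)
        w = build_contiguity_weights(vs, rule="queen")
        assert np.array_equal(w.matrix, w.matrix.T)
        for i in range(len(vs)):
            for j in range(len(vs)):
                if i == j:
                    continue
                touches = vs.geometries[i].intersection(
                    vs.geometries[j]
                ).is_empty is False
                assert bool(w.matrix[i, j]) == touches

    def test_rook_is_subset_of_queen(self):
        rng = np.random.default_rng(8)
        vs = random_voronoi(rng, 40)
        q = build_contiguity_weights(vs, rule="queen")
        r = build_contiguity_weights(vs, rule="rook")
        assert np.all(r.matrix <= q.matrix)

    def test_bad_rule_rejected(self):
        vs = square_lattice_villages(2, 2)
        with pytest.raises(ConfigError):
            build_contiguity_weights(vs, rule="bishop")


class TestMoransI:
    def test_checkerboard_is_minus_one(self, lattice_2x2_rook):
        # hand evaluation: numerator 4*(-2), denominator 8*1
        assert morans_i([1.0, 0.0, 0.0, 1.0], lattice_2x2_rook) == pytest.approx(-1.0)

    def test_two_blocks_cluster_positively(self):
        vs = square_lattice_villages(2, 4)
        w = build_contiguity_weights(vs, rule="rook")
        x = [1.0, 1.0, 0.0, 0.0, 1.0, 1.0, 0.0, 0.0]
        assert morans_i(x, w) > 0

    def test_matches_brute_force_on_random_fixtures(self):
        rng = np.random.default_rng(99)
        for _ in range(30):
            n = int(rng.integers(4, 13))
            m = (rng.random((n, n)) < 0.4).astype(float)
            m = np.triu(m, 1)
            m = m + m.T
            if m.sum() == 0:
                m[0, 1] = m[1, 0] = 1.0
            w = SpatialWeights([f"v{k}" for k in range(n)], m)
            x = rng.normal(size=n)
            assert morans_i(x, w) == pytest.approx(
                brute_force_morans_i(x, m), abs=1e-12
            )

    def test_constant_attribute_rejected(self, lattice_2x2_rook):
        with pytest.raises(NumericalError):
            morans_i([2.0, 2.0, 2.0, 2.0], lattice_2x2_rook)

    def test_order_permutation_invariance(self):
        rng = np.random.default_rng(3)
        vs = random_voronoi(rng, 20)
        w = build_contiguity_weights(vs)
        x = rng.normal(size=20)
        perm = rng.permutation(20)
        w2 = SpatialWeights(
            [w.ids[k] for k in perm], w.matrix[np.ix_(perm, perm)]
        )
        assert morans_i(x[perm], w2) == pytest.approx(morans_i(x, w), abs=1e-12)


class TestMoranInference:
    def test_permutation_is_seed_reproducible(self, lattice_2x2_rook):
        rng = np.random.default_rng(5)
        vs = random_voronoi(rng, 30)
        w = build_contiguity_weights(vs)
        x = rng.normal(size=30)
        a = morans_i_inference(x, w, n_perm=199, seed=7)
        b = morans_i_inference(x, w, n_perm=199, seed=7)
        assert (a.I, a.z_score, a.p_value) == (b.I, b.z_score, b.p_value)

    def test_p_value_never_zero(self):
        rng = np.random.default_rng(6)
        vs = random_voronoi(rng, 40)
        w = build_contiguity_weights(vs)
        x = np.array([g.centroid.x for g in vs.geometries])  # strong gradient
        res = morans_i_inference(x, w, n_perm=199, seed=1)
        assert res.p_value >= 2.0 / 200.0

    def test_clustered_field_is_highly_significant(self):
        rng = np.random.default_rng(12)
        vs = random_voronoi(rng, 120)
        w = build_contiguity_weights(vs)
        cents = vs.centroids()
        x = cents[:, 0] / 100.0 + rng.normal(scale=0.5, size=len(vs))
        res = morans_i_inference(x, w, n_perm=999, seed=2)
        assert res.p_value <= 2.0 / 1000.0

    def test_analytic_and_permutation_z_agree_in_sign(self):
        rng = np.random.default_rng(17)
        vs = random_voronoi(rng, 50)
        w = build_contiguity_weights(vs)
        for _ in range(5):
            x = rng.normal(size=50)
            za = morans_i_inference(x, w, method="analytic").z_score
            zp = morans_i_inference(x, w, n_perm=499, seed=3).z_score
            assert np.sign(za) == np.sign(zp)


class TestGiStar:
    def test_hand_oracle_on_path_graph(self, path_weights):
        x = [3.0, 8.0, 2.0, 9.0, 4.0]
        got = gi_star(x, path_weights)["z"].to_numpy()
        expected = brute_force_gi_star(x, path_weights.with_self().matrix)
        assert np.allclose(got, expected, atol=1e-12)

    def test_single_elevated_village_is_the_peak(self, path_weights):
        rng = np.random.default_rng(23)
        x = 10.0 + rng.normal(scale=1e-4, size=5)
        x[0] = 50.0  # elevate one village of the path
        z = gi_star(x, path_weights)["z"]
        assert z.index[np.argmax(z.to_numpy())] == path_weights.ids[0]
        # and it agrees with the literal formula evaluation
        expected = brute_force_gi_star(x, path_weights.with_self().matrix)
        assert np.allclose(z.to_numpy(), expected, atol=1e-12)

    def test_constant_attribute_rejected(self, path_weights):
        with pytest.raises(NumericalError):
            gi_star([5.0] * 5, path_weights)

    def test_order_permutation_invariance(self):
        rng = np.random.default_rng(31)
        vs = random_voronoi(rng, 15)
        w = build_contiguity_weights(vs)
        x = rng.normal(size=15)
        base = gi_star(x, w)
        perm = rng.permutation(15)
        w2 = SpatialWeights([w.ids[k] for k in perm], w.matrix[np.ix_(perm, perm)])
        shuffled = gi_star(x[perm], w2)
        for vid in w.ids:
            assert shuffled.loc[vid, "z"] == pytest.approx(
                base.loc[vid, "z"], abs=1e-12
            )

    def test_null_rejection_rate_is_nominal(self):
        """Under iid data the fraction of |z| > 1.96 stays near 5%."""
        rng = np.random.default_rng(2024)
        vs = random_voronoi(rng, 100)
        w = build_contiguity_weights(vs)
        flags = []
        for _ in range(60):
            x = rng.normal(size=100)
            z = gi_star(x, w)["z"].to_numpy()
            flags.append(np.mean(np.abs(z) > 1.96))
        assert 0.02 <= np.mean(flags) <= 0.09


class TestHotspotClasses:
    def test_threshold_lookup(self):
        gi = pd.DataFrame(
            {"z": [0.0, 2.0, -3.0, 2.6, -2.0], "p_value": [1.0] * 5},
            index=[f"v{k}" for k in range(5)],
        )
        out = classify_hotspots(gi)
        assert out["hotspot"].tolist() == ["ns", "hot95", "cold99", "hot99", "cold95"]

    def test_classes_monotone_in_z(self):
        zs = np.linspace(-4, 4, 81)
        gi = pd.DataFrame({"z": zs, "p_value": 1.0}, index=range(81))
        rank = {"cold99": 0, "cold95": 1, "ns": 2, "hot95": 3, "hot99": 4}
        ranks = [rank[c] for c in classify_hotspots(gi)["hotspot"]]
        assert ranks == sorted(ranks)


class TestPersistentHotspots:
    def _table(self, classes):
        idx = [f"v{k}" for k in range(len(classes))]
        return pd.DataFrame(
            {"z": 0.0, "p_value": 1.0, "hotspot": classes}, index=idx
        )

    def test_identical_hot_sets_returned(self):
        t = self._table(["hot99", "ns", "hot95", "cold95"])
        assert persistent_hotspots([t, t.copy(), t.copy()]) == ["v0", "v2"]

    def test_disjoint_hot_sets_empty(self):
        a = self._table(["hot95", "ns", "ns"])
        b = self._table(["ns", "hot95", "ns"])
        assert persistent_hotspots([a, b]) == []

    def test_mismatched_village_sets_rejected(self):
        a = self._table(["hot95", "ns"])
        b = self._table(["hot95", "ns", "ns"])
        with pytest.raises(DataError):
            persistent_hotspots([a, b])

    def test_persistent_subset_of_each_period(self, default_study):
        """With a fixed basin risk core, the persistent set is contained
        in every period's hot set."""
        from topoepi import crude_rates, spatial_eb_smooth

        study = default_study
        w = build_contiguity_weights(study.villages.subset(study.topography.index))
        mort = spatial_eb_smooth(crude_rates(study.mortality), w)
        tables = []
        for p in sorted(mort["period"].unique()):
            sub = mort[mort["period"] == p].set_index("village_id")
            sub = sub.loc[study.topography.index]
            tables.append(
                classify_hotspots(gi_star(sub["smoothed_rate"].to_numpy(), w))
            )
        persistent = set(persistent_hotspots(tables))
        assert persistent
        for t in tables:
            hot = {v for v, c in t["hotspot"].items() if c.startswith("hot")}
            assert persistent <= hot
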