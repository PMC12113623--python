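"""Bray-Curtis, haversine distances, distance-decay, Mantel tests, and the
classical-MDS spatial axis."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

from myconet.core import AsvTable, ValidationError
from myconet.spatial import (
    EARTH_RADIUS_KM,
    bray_curtis,
    classical_mds,
    distance_decay,
    geo_distance,
    mantel,
    mds_spatial_axis,
    partial_mantel,
)


def _table(rows, ids=None):
    arr = np.asarray(rows)
    return AsvTable(
        pd.DataFrame(
            arr,
            index=ids or [f"s{i}" for i in range(arr.shape[0])],
            columns=[f"a{j}" for j in range(arr.shape[1])],
        )
    )


def _meta(lats, lons):
    return pd.DataFrame(
        {
            "sample_id": [f"s{i}" for i in range(len(lats))],
            "habitat": ["alpine_meadow"] * len(lats),
            "latitude": lats,
            "longitude": lons,
        }
    )


def _random_dist(rng, n, dims=2):
    pts = rng.uniform(0, 10, size=(n, dims))
    return squareform(pdist(pts))


class TestBrayCurtis:
    def test_identical_samples_zero(self):
        bc = bray_curtis(_table([[3, 4], [3, 4]]))
        assert bc.iloc[0, 1] == pytest.approx(0.0)

    def test_disjoint_samples_one(self):
        bc = bray_curtis(_table([[5, 0], [0, 7]]))
        assert bc.iloc[0, 1] == pytest.approx(1.0)

    def test_hand_formula_third(self):
        bc = bray_curtis(_table([[1, 1], [1, 0]]))
        assert bc.iloc[0, 1] == pytest.approx(1 / 3, abs=1e-12)

    def test_range_and_symmetry(self, rng):
        counts = rng.integers(0, 30, size=(12, 20))
        counts[:, 0] += 1
        bc = bray_curtis(_table(counts)).to_numpy()
        assert np.allclose(bc, bc.T)
        assert np.allclose(np.diag(bc), 0.0)
        assert ((bc >= 0) & (bc <= 1)).all()


class TestGeoDistance:
    def test_identical_points_zero(self):
        d = geo_distance(_meta([30.0, 30.0], [85.0, 85.0]))
        assert d.iloc[0, 1] == pytest.approx(0.0)

    def test_one_degree_longitude_at_equator(self):
        d = geo_distance(_meta([0.0, 0.0], [0.0, 1.0]))
        assert d.iloc[0, 1] == pytest.approx(
            np.pi / 180 * EARTH_RADIUS_KM, abs=1e-3
        )
        assert d.iloc[0, 1] == pytest.approx(111.195, abs=1e-3)

    def test_metric_axioms_on_random_coordinates(self, rng):
        lats = rng.uniform(-60, 60, 8)
        lons = rng.uniform(-170, 170, 8)
        d = geo_distance(_meta(lats, lons)).to_numpy()
        assert np.allclose(d, d.T)
        assert (d >= 0).all()
        for i in range(8):
            for j in range(8):
                for k in range(8):
                    assert d[i, j] <= d[i, k] + d[k, j] + 1e-9

    def test_missing_coordinate_names_sample(self):
        meta = _meta([30.0, np.nan], [85.0, 85.0])
        with pytest.raises(ValidationError, match="s1"):
            geo_distance(meta)


class TestDistanceDecay:
    def _pairs_as_matrices(self, d_pairs, sim_pairs):
        """Embed pair values into valid symmetric matrices is awkward;
        instead build matrices directly from a vector layout."""
        n = int((1 + np.sqrt(1 + 8 * len(d_pairs))) / 2)
        geo = np.zeros((n, n))
        bc = np.zeros((n, n))
        iu = np.triu_indices(n, 1)
        geo[iu] = d_pairs
        geo.T[iu] = d_pairs
        bc[iu] = 1 - np.asarray(sim_pairs)
        bc.T[iu] = 1 - np.asarray(sim_pairs)
        return bc, geo

    def test_perfect_line_r2_one(self):
        d = np.array([10.0, 100.0, 1000.0])
        sim = 0.9 - 0.1 * np.log10(d)
        bc, geo = self._pairs_as_matrices(d, sim)
        res = distance_decay(bc, geo, "log10")
        assert res.r_squared == pytest.approx(1.0)
        assert res.slope == pytest.approx(-0.1)

    def test_planted_slope_recovered_within_ci(self, rng):
        n = 21  # 210 pairs
        d = rng.uniform(1, 1500, size=n * (n - 1) // 2)
        sim = 0.8 - 0.12 * np.log10(d) + rng.normal(0, 0.03, len(d))
        bc, geo = self._pairs_as_matrices(d, sim)
        res = distance_decay(bc, geo, "log10")
        lo, hi = res.slope_ci()
        assert lo <= -0.12 <= hi

    def test_unstructured_slope_within_two_se(self, rng):
        """Spatially unstructured pair similarities: |slope| < 2 SE in >= 90%
        of seeds (iid pairs, so the OLS band is exact)."""
        hits = 0
        n_pairs = 190
        for _ in range(100):
            d = rng.uniform(1, 1500, size=n_pairs)
            sim = 0.5 + rng.normal(0, 0.05, n_pairs)
            bc, geo = self._pairs_as_matrices(d, sim)
            res = distance_decay(bc, geo, "log10")
            hits += abs(res.slope) < 2 * res.slope_stderr
        assert hits >= 90

    def test_zero_distance_pairs_dropped_under_log(self):
        d = np.array([0.0, 100.0, 1000.0])
        sim = np.array([0.9, 0.5, 0.4])
        bc, geo = self._pairs_as_matrices(d, sim)
        with pytest.raises(ValidationError, match="3 usable pairs"):
            distance_decay(bc, geo, "log10")
        res = distance_decay(bc, geo, "identity")
        assert res.n_pairs == 3


class TestMantel:
    def test_self_comparison_is_perfect(self, rng):
        d = _random_dist(rng, 12)
        res = mantel(d, d, n_perm=99, seed=1)
        assert res.r == pytest.approx(1.0)
        assert res.p_value == pytest.approx(1 / 100)

    def test_deterministic_given_seed(self, rng):
        a, b = _random_dist(rng, 10), _random_dist(rng, 10)
        r1 = mantel(a, b, n_perm=199, seed=5)
        r2 = mantel(a, b, n_perm=199, seed=5)
        assert (r1.r, r1.p_value) == (r2.r, r2.p_value)

    def test_statistic_matches_skbio(self, rng):
        from skbio.stats.distance import DistanceMatrix
        from skbio.stats.distance import mantel as skbio_mantel

        a, b = _random_dist(rng, 15), _random_dist(rng, 15)
        ours = mantel(a, b, n_perm=99, seed=0)
        ref_r, _, _ = skbio_mantel(
            DistanceMatrix(a), DistanceMatrix(b),
            method="spearman", permutations=0,
        )
        assert ours.r == pytest.approx(float(ref_r), abs=1e-12)

    def test_non_symmetric_input_rejected(self, rng):
        a = _random_dist(rng, 6)
        bad = a.copy()
        bad[0, 1] += 1.0
        with pytest.raises(ValidationError, match="symmetric"):
            mantel(a, bad, n_perm=99)

    def test_type_one_error_calibration_light(self, rng):
        hits = 0
        reps = 200
        for _ in range(reps):
            a, b = _random_dist(rng, 12), _random_dist(rng, 12)
            if mantel(a, b, n_perm=99, seed=int(rng.integers(2**31))).p_value <= 0.05:
                hits += 1
        assert 0.02 <= hits / reps <= 0.09


class TestPartialMantel:
    def test_independent_control_leaves_r(self, rng):
        pts = rng.uniform(0, 10, size=(15, 2))
        a = squareform(pdist(pts))
        b = squareform(pdist(pts + rng.normal(0, 1.0, pts.shape)))
        c = _random_dist(rng, 15)
        simple = mantel(a, b, n_perm=99, seed=1).r
        partial = partial_mantel(a, b, c, n_perm=99, seed=1).r
        assert abs(simple - partial) < 0.15

    def test_control_explains_away_correlation(self, rng):
        c = _random_dist(rng, 15)
        b = c**2  # monotone function of the control
        a = squareform(pdist(rng.uniform(0, 10, size=(15, 2))))
        res = partial_mantel(a, b, c, n_perm=99, seed=2)
        assert abs(res.r) < 0.05

    def test_identical_matrices_near_one(self, rng):
        a = _random_dist(rng, 15)
        c = _random_dist(rng, 15)
        res = partial_mantel(a, a, c, n_perm=99, seed=3)
        assert res.r > 0.95
        assert res.p_value == pytest.approx(1 / 100)


class TestMdsSpatialAxis:
    def test_collinear_points_single_axis(self):
        axis = mds_spatial_axis(_meta([28.0, 29.0, 30.5, 33.0], [85.0] * 4))
        assert axis.variance_fraction == pytest.approx(1.0)

    def test_scores_are_z_scored(self, rng):
        meta = _meta(rng.uniform(28, 34, 10), rng.uniform(80, 92, 10))
        axis = mds_spatial_axis(meta)
        assert axis.scores.mean() == pytest.approx(0.0, abs=1e-9)
        assert axis.scores.std(ddof=0) == pytest.approx(1.0, abs=1e-9)

    def test_euclidean_configuration_reproduced(self, rng):
        pts = rng.uniform(0, 5, size=(12, 2))
        d = squareform(pdist(pts))
        coords, vals = classical_mds(d)
        again = squareform(pdist(coords))
        assert np.allclose(again, d, atol=1e-9)

    def test_axis_matches_skbio_pcoa(self, rng):
        from skbio.stats.ordination import pcoa

        meta = _meta(rng.uniform(28, 34, 10), rng.uniform(80, 92, 10))
        axis = mds_spatial_axis(meta)
        coords = meta[["latitude", "longitude"]].to_numpy()
        ref = pcoa(squareform(pdist(coords)), method="eigh")
        ref_axis = ref.samples.iloc[:, 0].to_numpy()
        corr = np.corrcoef(axis.scores, ref_axis)[0, 1]
        assert abs(corr) == pytest.approx(1.0, abs=1e-9)
        assert axis.variance_fraction == pytest.approx(
            float(ref.proportion_explained.iloc[0]), abs=1e-6
        )

    def test_coincident_points_degenerate(self):
        with pytest.raises(ValidationError, match="degenerate|coincide"):
            mds_spatial_axis(_meta([30.0] * 4, [85.0] * 4))
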