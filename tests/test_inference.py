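"""Edge inference: abundance filter, Spearman/KLD matrices, permutation
p-values, BH correction, and the three-clause network construction."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from myconet.core import AsvTable, ValidationError
from myconet.inference import (
    EdgeCandidateMatrices,
    bh_adjust,
    bh_adjust_matrix,
    build_network,
    edge_candidates,
    filter_low_abundance,
    kld_matrix,
    resampling_pvalues,
    spearman_matrix,
)


def _table(columns: dict, n_samples: int | None = None) -> AsvTable:
    df = pd.DataFrame(columns)
    df.index = [f"s{i}" for i in range(len(df))]
    return AsvTable(df)


class TestAbundanceFilter:
    def test_boundary_is_strict(self):
        # grand total 10000: 1 read = exactly 0.01% -> removed; 2 reads kept
        table = _table({"big": [9497, 500], "one": [1, 0], "two": [2, 0]})
        kept = filter_low_abundance(table, 1e-4)
        assert kept.asv_ids == ["big", "two"]

    def test_matches_brute_force(self, rng):
        counts = rng.integers(0, 50, size=(15, 40))
        counts[:, 0] += 1
        table = AsvTable(
            pd.DataFrame(counts, index=[f"s{i}" for i in range(15)],
                         columns=[f"a{j}" for j in range(40)])
        )
        kept = filter_low_abundance(table, 0.02)
        grand = counts.sum()
        brute = [f"a{j}" for j in range(40) if counts[:, j].sum() / grand > 0.02]
        assert kept.asv_ids == brute

    def test_removing_everything_is_error(self):
        table = _table({"a": [5, 5], "b": [5, 5]})
        with pytest.raises(ValidationError, match="every ASV"):
            filter_low_abundance(table, 0.9)


class TestSpearmanMatrix:
    def test_identical_and_reversed_profiles(self):
        table = _table({"up": [1, 2, 3, 4], "same": [2, 4, 6, 8],
                        "down": [8, 6, 4, 2]})
        rho = spearman_matrix(table, abundance_mode="counts")
        assert rho.at["up", "same"] == pytest.approx(1.0)
        assert rho.at["up", "down"] == pytest.approx(-1.0)

    def test_hand_rank_example(self):
        table = _table({"x": [1, 2, 3, 4], "y": [1, 3, 2, 4]})
        rho = spearman_matrix(table, abundance_mode="counts")
        assert rho.at["x", "y"] == pytest.approx(0.8)

    def test_matches_scipy_on_random_table(self, rng):
        counts = rng.integers(0, 20, size=(25, 12))
        counts[:, 0] += 1
        table = AsvTable(
            pd.DataFrame(counts, index=[f"s{i}" for i in range(25)],
                         columns=[f"a{j}" for j in range(12)])
        )
        ours = spearman_matrix(table, abundance_mode="counts").to_numpy()
        ref = stats.spearmanr(counts).statistic
        assert np.allclose(ours, ref, atol=1e-10)

    def test_constant_profile_excluded(self):
        table = _table({"flat": [3, 3, 3, 3], "var": [1, 2, 3, 4],
                        "var2": [4, 1, 2, 3]})
        rho = spearman_matrix(table, abundance_mode="counts")
        assert rho["flat"].isna().all()
        mats = edge_candidates(
            AsvTable(table.counts), n_resamples=100, seed=1,
            abundance_mode="counts",
        )
        net = build_network(mats, rho_threshold=0.0, alpha=1.0)
        assert "flat" not in net.graph.nodes


class TestKldMatrix:
    def test_identical_profiles_zero(self):
        table = _table({"a": [2, 2], "b": [5, 5]})
        kld = kld_matrix(table, pseudocount=1e-12, abundance_mode="counts")
        assert kld.at["a", "b"] == pytest.approx(0.0, abs=1e-9)

    def test_hand_formula_value(self):
        # profiles (0.5, 0.5) vs (0.25, 0.75)
        table = _table({"a": [1, 1], "b": [1, 3]})
        kld = kld_matrix(table, pseudocount=1e-12, abundance_mode="counts")
        expected = 0.5 * (
            0.5 * np.log(0.5 / 0.25) + 0.5 * np.log(0.5 / 0.75)
            + 0.25 * np.log(0.25 / 0.5) + 0.75 * np.log(0.75 / 0.5)
        )
        assert kld.at["a", "b"] == pytest.approx(expected, abs=1e-9)
        assert kld.at["a", "b"] == pytest.approx(0.13733, abs=1e-4)

    def test_symmetric_nonnegative_zero_diagonal(self, rng):
        counts = rng.integers(0, 30, size=(10, 8))
        counts[:, 0] += 1
        table = AsvTable(
            pd.DataFrame(counts, index=[f"s{i}" for i in range(10)],
                         columns=[f"a{j}" for j in range(8)])
        )
        kld = kld_matrix(table).to_numpy()
        assert np.allclose(kld, kld.T)
        assert (kld >= 0).all()
        assert np.allclose(np.diag(kld), 0.0)

    def test_pseudocount_must_be_positive(self, toy_table):
        with pytest.raises(ValidationError, match="pseudocount"):
            kld_matrix(toy_table, pseudocount=0.0)


class TestResamplingPvalues:
    def test_deterministic_given_seed(self, toy_table):
        a = resampling_pvalues(toy_table, 200, seed=9)
        b = resampling_pvalues(toy_table, 200, seed=9)
        assert a.equals(b)

    def test_duplicated_pair_attains_minimum(self, rng):
        x = rng.integers(1, 100, size=50)
        table = _table({"a": x, "b": x})
        p = resampling_pvalues(table, 1000, seed=2, abundance_mode="counts")
        assert p.at["a", "b"] == pytest.approx(1 / 1001)

    def test_null_calibration(self, rng):
        """Raw permutation p-values are uniform on independent profiles."""
        counts = rng.poisson(50, size=(60, 60)) + 1
        table = AsvTable(
            pd.DataFrame(counts, index=[f"s{i}" for i in range(60)],
                         columns=[f"a{j}" for j in range(60)])
        )
        p = resampling_pvalues(table, 500, seed=3, abundance_mode="counts")
        iu = np.triu_indices(60, 1)
        frac = (p.to_numpy()[iu] < 0.05).mean()
        # 1770 pairs; binomial 3-sigma band around 0.05
        assert abs(frac - 0.05) < 3 * np.sqrt(0.05 * 0.95 / 1770) + 0.005

    def test_too_few_resamples_rejected(self, toy_table):
        with pytest.raises(ValidationError, match="n_resamples"):
            resampling_pvalues(toy_table, 50)


def _bh_oracle(p):
    """Independent step-up implementation for cross-checking."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p)
    q = np.empty(m)
    prev = 1.0
    for rank_from_top in range(m, 0, -1):
        idx = order[rank_from_top - 1]
        val = min(prev, p[idx] * m / rank_from_top)
        q[idx] = val
        prev = val
    return np.minimum(q, 1.0)


class TestBhAdjust:
    def test_hand_step_up_example(self):
        assert bh_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_all_ones(self):
        assert bh_adjust(np.ones(5)) == pytest.approx(np.ones(5))

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_independent_oracle(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.uniform(size=200)
        assert bh_adjust(p) == pytest.approx(_bh_oracle(p), abs=1e-12)

    def test_matrix_adjustment_never_below_raw(self, planted_data):
        p = resampling_pvalues(planted_data.table.subset_asvs(
            planted_data.table.asv_ids[:30]), 200, seed=5)
        q = bh_adjust_matrix(p)
        iu = np.triu_indices(30, 1)
        assert (q.to_numpy()[iu] + 1e-12 >= p.to_numpy()[iu]).all()


class TestBuildNetwork:
    def _mats(self, rho, q=None, kld=None):
        ids = [f"a{i}" for i in range(rho.shape[0])]
        if q is None:
            q = np.full_like(rho, 1e-4)
            np.fill_diagonal(q, np.nan)
        if kld is None:
            kld = np.zeros_like(rho)
        wrap = lambda m: pd.DataFrame(m, index=ids, columns=ids)
        return EdgeCandidateMatrices(
            asv_ids=ids, rho=wrap(rho), kld=wrap(kld),
            p_raw=wrap(q), q=wrap(q),
        )

    def test_threshold_is_strictly_applied(self):
        rho = np.full((4, 4), 0.59)
        np.fill_diagonal(rho, 1.0)
        assert build_network(self._mats(rho), rho_threshold=0.6).n_edges == 0

    def test_negative_edges_retained_by_magnitude(self):
        rho = np.array([[1.0, -0.7], [-0.7, 1.0]])
        net = build_network(self._mats(rho), rho_threshold=0.6)
        assert net.n_edges == 1
        assert net.graph["a0"]["a1"]["sign"] == "-"

    def test_kld_max_mode_is_vacuous(self, planted_data):
        table = planted_data.table.subset_asvs(planted_data.table.asv_ids[:40])
        mats = edge_candidates(table, n_resamples=200, seed=4)
        by_max = build_network(mats, kld_mode="max")
        by_q1 = build_network(mats, kld_mode="quantile:1.0")
        assert by_max.edge_set() == by_q1.edge_set()

    def test_kld_quantile_mode_restricts(self, planted_data):
        table = planted_data.table.subset_asvs(planted_data.table.asv_ids[:40])
        mats = edge_candidates(table, n_resamples=200, seed=4)
        loose = build_network(mats, kld_mode="max")
        tight = build_network(mats, kld_mode="quantile:0.25")
        assert tight.edge_set() <= loose.edge_set()

    def test_edge_count_monotone_in_thresholds(self, planted_data):
        table = planted_data.table.subset_asvs(planted_data.table.asv_ids[:40])
        mats = edge_candidates(table, n_resamples=300, seed=8)
        counts = [
            build_network(mats, rho_threshold=t).n_edges
            for t in (0.0, 0.3, 0.6, 0.9)
        ]
        assert counts == sorted(counts, reverse=True)
        by_alpha = [
            build_network(mats, rho_threshold=0.3, alpha=a).n_edges
            for a in (0.1, 0.05, 0.01)
        ]
        assert by_alpha == sorted(by_alpha, reverse=True)

    def test_candidate_matrix_invariants(self, planted_data):
        table = planted_data.table.subset_asvs(planted_data.table.asv_ids[:25])
        mats = edge_candidates(table, n_resamples=200, seed=6)
        mats.check_invariants()  # symmetry, kld >= 0, q >= p
        assert np.allclose(np.diag(mats.rho.to_numpy()), 1.0)
        assert np.allclose(np.diag(mats.kld.to_numpy()), 0.0)
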