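"""Consensus clustering: base clusterer, consensus matrix, CDF statistics,
k selection and final label assignment."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import adjusted_rand_score

from subtypeforge import ConsensusCluster, Platform, zscore_rows
from subtypeforge.consensus import (CDF_GRID, ambiguity_score, auc_and_delta,
                                    base_cluster, build_consensus,
                                    consensus_cdf, final_labels,
                                    select_optimal_k)


def two_blob_matrix(n_per=5, n_features=20, gap=10.0, seed=0):
    """Two groups of samples, each with its own up-shifted feature block."""
    rng = np.random.default_rng(seed)
    x = rng.normal(size=(n_features, 2 * n_per))
    x[: n_features // 2, :n_per] += gap
    x[n_features // 2:, n_per:] += gap
    return x


class TestBaseCluster:
    def test_separated_blobs_recovered(self):
        x = two_blob_matrix()
        labels = base_cluster(x, 2)
        assert len(set(labels[:5])) == 1
        assert len(set(labels[5:])) == 1
        assert labels[0] != labels[5]

    def test_n_equals_k_forces_singletons(self):
        x = np.random.default_rng(0).normal(size=(10, 4))
        labels = base_cluster(x, 4)
        assert len(set(labels)) == 4

    def test_duplicated_columns_co_cluster(self):
        rng = np.random.default_rng(1)
        base = rng.normal(size=(15, 5))
        x = np.hstack([base, base[:, [0]]])  # col 5 duplicates col 0
        labels = base_cluster(x, 3)
        assert labels[5] == labels[0]

    def test_k_larger_than_n_rejected(self):
        x = np.random.default_rng(0).normal(size=(5, 3))
        with pytest.raises(ValueError, match="exceeds"):
            base_cluster(x, 4)

    def test_constant_profile_rejected(self):
        x = np.ones((5, 3))
        x[:, 0] = np.random.default_rng(0).normal(size=5)
        with pytest.raises(ValueError, match="constant"):
            base_cluster(x, 2)


class TestBuildConsensus:
    def test_full_fraction_gives_binary_entries(self):
        x = two_blob_matrix()
        cm = build_consensus(x, 2, n_resamples=7, subsample_fraction=1.0,
                             seed=0)
        assert set(np.unique(cm.M)) <= {0.0, 1.0}

    def test_full_fraction_b1_equals_b100(self):
        x = two_blob_matrix(seed=3)
        m1 = build_consensus(x, 2, n_resamples=1, subsample_fraction=1.0,
                             seed=0).M
        m100 = build_consensus(x, 2, n_resamples=100, subsample_fraction=1.0,
                               seed=5).M
        np.testing.assert_array_equal(m1, m100)

    def test_determinism(self):
        x = two_blob_matrix(seed=2)
        a = build_consensus(x, 2, n_resamples=10, seed=7)
        b = build_consensus(x, 2, n_resamples=10, seed=7)
        np.testing.assert_array_equal(a.M, b.M)

    @pytest.mark.parametrize("n,B,k", [(5, 2, 2), (6, 3, 2), (6, 3, 3)])
    def test_brute_force_enumeration_oracle(self, n, B, k):
        """M recomputed exhaustively from the recorded resamples."""
        rng = np.random.default_rng(n * 100 + B)
        x = rng.normal(size=(12, n))
        cm = build_consensus(x, k, n_resamples=B, subsample_fraction=0.8,
                             seed=1, keep_resamples=True)
        pair = np.zeros((n, n))
        co = np.zeros((n, n))
        for idx, _ in cm.resamples:
            labels = base_cluster(x[:, idx], k)  # independent re-clustering
            for ii, i in enumerate(idx):
                for jj, j in enumerate(idx):
                    pair[i, j] += 1
                    if labels[ii] == labels[jj]:
                        co[i, j] += 1
        expected = np.where(pair > 0, co / np.maximum(pair, 1), 0.0)
        np.testing.assert_array_equal(cm.M, expected)
        np.testing.assert_array_equal(cm.pair_counts, pair)

    @settings(max_examples=10, deadline=None)
    @given(seed=st.integers(0, 1000))
    def test_symmetry_and_range(self, seed):
        x = np.random.default_rng(seed).normal(size=(10, 8))
        cm = build_consensus(x, 2, n_resamples=5, seed=seed)
        np.testing.assert_array_equal(cm.M, cm.M.T)
        assert cm.M.min() >= 0 and cm.M.max() <= 1


class TestCDFStatistics:
    def test_all_ones_consensus_step_function(self):
        M = np.ones((4, 4))
        cdf = consensus_cdf(M)
        assert cdf[-1] == 1.0
        assert (cdf[:-1] == 0.0).all()

    def test_half_zero_half_one(self):
        M = np.zeros((4, 4))
        np.fill_diagonal(M, 1.0)
        # pairs (0,1),(2,3) -> 1; the other four -> 0
        for i, j in [(0, 1), (2, 3)]:
            M[i, j] = M[j, i] = 1.0
        cdf = consensus_cdf(M)
        # 2 of 6 pairs at 1
        assert cdf[0] == pytest.approx(4 / 6)
        assert cdf[50] == pytest.approx(4 / 6)
        assert cdf[-1] == 1.0

    def test_mixed_matches_direct_count(self):
        rng = np.random.default_rng(0)
        M = rng.random((6, 6))
        M = (M + M.T) / 2
        np.fill_diagonal(M, 1.0)
        cdf = consensus_cdf(M)
        vals = M[np.triu_indices(6, k=1)]
        for gi, g in enumerate(CDF_GRID):
            assert cdf[gi] == pytest.approx((vals <= g).mean())

    def test_ambiguity_binary_consensus_is_zero(self):
        cdf = consensus_cdf(np.ones((4, 4)))
        assert ambiguity_score(cdf) == 0.0

    def test_ambiguity_all_half_is_one(self):
        M = np.full((4, 4), 0.5)
        np.fill_diagonal(M, 1.0)
        assert ambiguity_score(consensus_cdf(M)) == 1.0

    def test_ambiguity_uniform_values_near_08(self):
        rng = np.random.default_rng(0)
        n = 200
        M = np.zeros((n, n))
        iu = np.triu_indices(n, k=1)
        M[iu] = rng.random(len(iu[0]))
        M = M + M.T
        np.fill_diagonal(M, 1.0)
        # uniform consensus: CDF(0.9) - CDF(0.1) = 0.8 analytically
        assert ambiguity_score(consensus_cdf(M)) == pytest.approx(0.8,
                                                                  abs=0.02)

    def test_auc_of_all_ones_step(self):
        cdf = consensus_cdf(np.ones((4, 4)))
        auc, delta = auc_and_delta({2: cdf})
        # trapezoid of a step at the last grid cell: 0.5 * 0.01 * 1
        assert auc[2] == pytest.approx(0.005)
        assert delta[2] == pytest.approx(0.005)

    def test_identical_cdfs_give_zero_delta(self):
        cdf = consensus_cdf(np.ones((4, 4)))
        _, delta = auc_and_delta({2: cdf, 3: cdf.copy()})
        assert delta[3] == 0.0

    def test_single_k_delta_is_raw_area(self):
        cdf = np.linspace(0, 1, len(CDF_GRID))
        auc, delta = auc_and_delta({4: cdf})
        assert delta[4] == auc[4]

    def test_empty_scan_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            auc_and_delta({})
        with pytest.raises(ValueError, match="empty"):
            select_optimal_k({})


class TestKSelection:
    def test_tie_breaks_toward_smaller_k_without_delta_plot(self):
        chosen, low = select_optimal_k({2: 0.3, 3: 0.3, 4: 0.5})
        assert chosen == 2
        assert not low

    def test_exact_tie_resolved_by_delta_plot(self):
        """A stable nested merge ties the ambiguity at two k; a substantial
        delta-area gain promotes the finer partition."""
        amb = {2: 0.0, 3: 0.0, 4: 0.05}
        delta = {2: 0.45, 3: 0.49, 4: 0.02}
        chosen, _ = select_optimal_k(amb, delta)
        assert chosen == 3
        # negligible gain: stay at the coarser partition
        chosen, _ = select_optimal_k(amb, {2: 0.45, 3: 0.01, 4: 0.02})
        assert chosen == 2

    def test_low_confidence_flag(self):
        chosen, low = select_optimal_k({2: 0.8, 3: 0.7})
        assert chosen == 3
        assert low

    def test_noise_cohort_is_low_confidence_everywhere(self):
        ambs = []
        for seed in range(5):
            x = np.random.default_rng(seed).normal(size=(50, 40))
            cc = ConsensusCluster(k_min=2, k_max=5, n_resamples=30,
                                  random_state=seed).fit(x.T)
            ambs.append(min(cc.scan_.ambiguity.values()))
        assert np.median(ambs) > 0.4


class TestFinalLabels:
    def test_block_diagonal_recovered(self):
        M = np.zeros((9, 9))
        for block in (slice(0, 4), slice(4, 7), slice(7, 9)):
            M[block, block] = 1.0
        from subtypeforge.consensus import ConsensusMatrix
        cm = ConsensusMatrix(k=3, M=M, pair_counts=np.ones((9, 9), int),
                             co_counts=(M > 0).astype(int))
        labels = final_labels(cm)
        # renumbered by descending size: block of 4 -> 1, of 3 -> 2, of 2 -> 3
        assert list(labels) == [1] * 4 + [2] * 3 + [3] * 2

    def test_duplicated_samples_co_labeled(self):
        rng = np.random.default_rng(4)
        base = rng.normal(size=(20, 6))
        x = np.hstack([base, base[:, [0, 1]]])
        cm = build_consensus(x, 3, n_resamples=20, seed=0)
        labels = final_labels(cm)
        assert labels[6] == labels[0]
        assert labels[7] == labels[1]


class TestEstimatorRecovery:
    def test_three_subtype_recovery(self, default_cohort):
        prot = zscore_rows(default_cohort.matrices[Platform.protein])
        cc = ConsensusCluster(random_state=0).fit(prot.values.T)
        truth = [default_cohort.true_labels[s] for s in prot.sample_ids]
        assert cc.chosen_k_ == 3
        assert adjusted_rand_score(truth, cc.labels_) >= 0.9
        assert not cc.low_confidence_

    def test_sklearn_get_set_params(self):
        cc = ConsensusCluster(k_max=5)
        params = cc.get_params()
        assert params["k_max"] == 5
        cc.set_params(n_resamples=10)
        assert cc.n_resamples == 10
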