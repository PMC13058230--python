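"""Two-sample t machinery, the two-of-three marker rule, knockdown gene
selection and the small correlation / qPCR utilities."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from subtypeforge import (CohortConfig, KnockdownConfig, Platform,
                          ddct_fold_change, generate_cohort,
                          generate_knockdown, pairwise_subtype_tests,
                          pearson_correlation, select_dependent_genes,
                          select_subtype_markers, students_t)
from subtypeforge.signatures import MRNA_THRESHOLDS, SubtypeMarkerSelector


class TestStudentsT:
    def test_identical_groups(self):
        t, p, df = students_t([1, 2, 3], [1, 2, 3])
        assert t == 0 and p == pytest.approx(1.0) and df == 4

    def test_hand_computed_example(self):
        t, p, df = students_t([1, 2, 3, 4], [3, 4, 5, 6])
        assert t == pytest.approx(-2.19089, abs=1e-4)
        assert df == 6

    def test_zero_variance_unequal_means_rejected(self):
        with pytest.raises(ValueError, match="pooled variance"):
            students_t([0, 0], [1, 1])

    def test_zero_variance_equal_means_degenerates(self):
        t, p, _ = students_t([2, 2], [2, 2])
        assert t == 0 and p == 1

    def test_matches_scipy(self):
        from scipy import stats
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=8), rng.normal(size=5)
        t, p, _ = students_t(x, y)
        ref = stats.ttest_ind(x, y, equal_var=True)
        assert t == pytest.approx(ref.statistic, abs=1e-12)
        assert p == pytest.approx(ref.pvalue, abs=1e-12)

    @settings(max_examples=30, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_antisymmetry(self, seed):
        rng = np.random.default_rng(seed)
        x, y = rng.normal(size=6), rng.normal(size=4)
        t1, p1, _ = students_t(x, y)
        t2, p2, _ = students_t(y, x)
        assert t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2)


class TestPairwiseTests:
    def test_result_count(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(100, 30))
        labels = np.repeat([1, 2, 3], 10)
        results = pairwise_subtype_tests(x, labels)
        assert len(results) == 300  # 100 features x 3 pairs

    def test_constant_feature_is_null(self):
        x = np.vstack([np.ones(12),
                       np.random.default_rng(0).normal(size=12)])
        labels = np.repeat([1, 2, 3], 4)
        res = pairwise_subtype_tests(x, labels)
        f0 = res[res["feature_id"] == "f0"]
        assert (f0["t_stat"] == 0).all() and (f0["p_value"] == 1).all()

    def test_planted_marker_hits_both_pairs(self):
        rng = np.random.default_rng(1)
        x = rng.normal(scale=0.1, size=(5, 30))
        labels = np.repeat([1, 2, 3], 10)
        x[0, labels == 2] += 3.0
        res = pairwise_subtype_tests(x, labels)
        f0 = res[res["feature_id"] == "f0"]
        involving_2 = f0[(f0["a"] == 2) | (f0["b"] == 2)]
        assert (involving_2["p_value"] < 1e-6).all()

    def test_small_group_rejected(self):
        x = np.random.default_rng(0).normal(size=(5, 5))
        with pytest.raises(ValueError, match="< 2 samples"):
            pairwise_subtype_tests(x, np.array([1, 1, 2, 2, 3]))


class TestMarkerRule:
    @staticmethod
    def planted(effect=3.0, noise=0.1, n_per=10, n_features=9, seed=0):
        rng = np.random.default_rng(seed)
        x = rng.normal(scale=noise, size=(n_features, 3 * n_per))
        labels = np.repeat([1, 2, 3], n_per)
        for s in (1, 2, 3):
            rows = slice((s - 1) * 2, s * 2)  # features 0-1 / 2-3 / 4-5
            x[rows, labels == s] += effect
        return x, labels

    def test_planted_markers_recovered_exactly(self):
        x, labels = self.planted()
        res = pairwise_subtype_tests(x, labels)
        sig = select_subtype_markers(res, p_cut=0.001, fold_cut_log2=1.0)
        assert sig.features_for(1) == ["f0", "f1"]
        assert sig.features_for(2) == ["f2", "f3"]
        assert sig.features_for(3) == ["f4", "f5"]
        assert all(d == "up"
                   for s in (1, 2, 3)
                   for d in sig.markers[s]["direction"])

    def test_single_pair_significance_excluded(self):
        """A feature separating subtype 2 from 3 but not from 1 is no marker."""
        rng = np.random.default_rng(0)
        x = rng.normal(scale=0.1, size=(1, 30))
        labels = np.repeat([1, 2, 3], 10)
        x[0, labels == 2] += 3.0
        x[0, labels == 1] += 3.0  # same shift in 1: pair (1,2) is null
        res = pairwise_subtype_tests(x, labels)
        sig = select_subtype_markers(res, p_cut=0.001, fold_cut_log2=1.0)
        assert sig.features_for(2) == []

    def test_direction_consistency_required(self):
        """A graded feature (high in 1, middling in 2, low in 3) is up AND
        down relative to subtype 2, so it cannot mark subtype 2; for the
        extreme subtypes it is consistent and collides, landing in one."""
        rng = np.random.default_rng(0)
        x = rng.normal(scale=0.05, size=(1, 30))
        labels = np.repeat([1, 2, 3], 10)
        x[0, labels == 1] += 3.0
        x[0, labels == 2] += 1.5
        res = pairwise_subtype_tests(x, labels)
        strict = select_subtype_markers(res, 0.001, 1.0)
        assert strict.features_for(2) == []
        assert "f0" in strict.collisions          # qualifies for 1 and 3
        assert len(strict.all_features()) == 1    # but assigned only once
        relaxed = select_subtype_markers(res, 0.001, 1.0,
                                         require_direction=False)
        assert len(relaxed.all_features()) == 1   # subtype 2 now also a
        assert "f0" in relaxed.collisions         # candidate, still 1 home

    def test_fold_cut_filters(self):
        x, labels = self.planted(effect=0.5)  # significant but small fold
        res = pairwise_subtype_tests(x, labels)
        sig = select_subtype_markers(res, p_cut=0.001, fold_cut_log2=1.0)
        assert sig.all_features() == []

    def test_invariance_to_sample_order_and_offset(self):
        x, labels = self.planted(seed=3)
        res1 = pairwise_subtype_tests(x, labels)
        perm = np.random.default_rng(0).permutation(x.shape[1])
        res2 = pairwise_subtype_tests(x[:, perm] + 7.0, labels[perm])
        sig1 = select_subtype_markers(res1, 0.001, 1.0)
        sig2 = select_subtype_markers(res2, 0.001, 1.0)
        for s in (1, 2, 3):
            assert sig1.features_for(s) == sig2.features_for(s)

    def test_default_cohort_recovery(self, default_cohort):
        mrna = default_cohort.matrices[Platform.mrna]
        labels = np.array([default_cohort.true_labels[s]
                           for s in mrna.sample_ids])
        res = pairwise_subtype_tests(mrna, labels)
        sig = select_subtype_markers(res, *MRNA_THRESHOLDS)
        planted = default_cohort.planted_markers
        tp = fp = fn = 0
        for s in (1, 2, 3):
            found = set(sig.features_for(s))
            true = set(planted[s])
            tp += len(found & true)
            fn += len(true - found)
            # the amplified driver legitimately marks subtype 1
            fp += len(found - true - {"DRIVER"})
        sensitivity = tp / (tp + fn)
        fdr = fp / max(tp + fp, 1)
        assert sensitivity >= 0.95
        assert fdr <= 0.05

    def test_selector_estimator_api(self):
        x, labels = self.planted()
        sel = SubtypeMarkerSelector(p_cut=0.001, fold_cut_log2=1.0)
        sel.fit(x.T, labels)
        assert sel.selected_features_ == [f"f{i}" for i in range(6)]
        assert sel.transform(x.T).shape == (30, 6)


class TestDependentGenes:
    def test_identical_arms_empty(self):
        arm = np.random.default_rng(0).normal(size=(50, 3))
        assert len(select_dependent_genes(arm, arm.copy())) == 0

    def test_saturated_construction_recovers_all(self):
        cfg = KnockdownConfig(n_genes=500, n_dependent=50, effect_size=5.0,
                              noise_sd=0.1, n_replicates=3, seed=2)
        m, arms = generate_knockdown(cfg)
        arms = np.array(arms)
        hits = select_dependent_genes(m.values[:, arms == "control"],
                                      m.values[:, arms == "knockdown"],
                                      p_cut=0.001,
                                      feature_ids=m.feature_ids)
        found = set(hits["feature_id"])
        planted = set(m.feature_ids[:50])
        assert planted <= found                      # every planted gene hit
        assert len(found - planted) <= 3             # nulls only at ~p_cut rate

    def test_null_type_one_rate(self):
        counts = []
        for seed in range(100):
            cfg = KnockdownConfig(n_genes=1000, n_dependent=0,
                                  n_replicates=4, seed=seed)
            m, arms = generate_knockdown(cfg)
            arms = np.array(arms)
            hits = select_dependent_genes(m.values[:, arms == "control"],
                                          m.values[:, arms == "knockdown"],
                                          p_cut=0.001)
            counts.append(len(hits))
        # expected 1 hit per 1000 null genes
        assert np.mean(counts) == pytest.approx(1.0, abs=0.5)

    def test_single_replicate_rejected(self):
        with pytest.raises(ValueError, match="replicates"):
            select_dependent_genes(np.ones((5, 1)), np.ones((5, 3)))


class TestCorrelation:
    def test_affine_relation(self):
        x = np.arange(5.0)
        r, p, n = pearson_correlation(x, 2 * x + 1)
        assert r == pytest.approx(1.0)

    def test_negative(self):
        x = np.arange(5.0)
        r, _, _ = pearson_correlation(x, -x)
        assert r == pytest.approx(-1.0)

    def test_hand_computed(self):
        # cov = 8, sx^2 = 10, sy^2 = 10 -> r = 0.8
        r, p, n = pearson_correlation([1, 2, 3, 4, 5], [2, 1, 4, 3, 5])
        assert r == pytest.approx(0.8)
        assert n == 5
        # p from t = r sqrt((n-2)/(1-r^2))
        from scipy import stats
        t = 0.8 * np.sqrt(3 / (1 - 0.64))
        assert p == pytest.approx(2 * stats.t.sf(t, 3), abs=1e-10)

    def test_constant_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            pearson_correlation([1, 1, 1], [1, 2, 3])


class TestDdct:
    @pytest.mark.parametrize("args,expected", [
        ((20, 15, 20, 15), 1.0),    # ddCt = 0
        ((22, 15, 20, 15), 0.25),   # ddCt = +2
        ((18, 15, 20, 15), 4.0),    # ddCt = -2
    ])
    def test_hand_arithmetic(self, args, expected):
        assert ddct_fold_change(*args) == pytest.approx(expected)
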