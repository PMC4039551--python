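"""Trial data generation, merge application and analysis-set construction."""

import dataclasses

import numpy as np
import pytest

from clustermerge.design import TrialDesign, merged_size_variance
from clustermerge.simulate import (
    EXCLUDED,
    MergeSpec,
    apply_heterogeneous_merges,
    apply_homogeneous_merges,
    build_analysis_set,
    generate_trial,
)


class TestGenerateTrial:
    def test_degenerate_noise_returns_arm_means_exactly(self, base_design):
        d = dataclasses.replace(base_design, sigma_b2=0.0, sigma_w2=1e-300)
        data = generate_trial(d, mu0=1.5, mu1=-0.5, seed=0)
        assert np.allclose(data.outcome[data.orig_arm == 0], 1.5)
        assert np.allclose(data.outcome[data.orig_arm == 1], -0.5)

    def test_same_seed_is_bit_identical(self, base_design):
        a = generate_trial(base_design, seed=123)
        b = generate_trial(base_design, seed=123)
        assert np.array_equal(a.outcome, b.outcome)
        assert np.array_equal(a.orig_cluster, b.orig_cluster)

    def test_structure(self, base_design):
        data = generate_trial(base_design, seed=0)
        assert data.n_subjects == 80 * 20
        sizes = data.analysis_cluster_sizes()
        assert sizes.size == 80 and set(sizes) == {20}
        assert (np.bincount(data.orig_arm[::20]) == [40, 40]).all()
        assert data.completer.all()

    def test_cluster_mean_variance_matches_law_of_total_variance(self, base_design):
        # var of cluster means of (Y - mu) is sigma_b2 + sigma_w2 / m
        d = dataclasses.replace(base_design, c=2000)
        data = generate_trial(d, mu0=0.0, mu1=0.2, seed=7)
        centred = data.outcome - np.where(data.orig_arm == 1, 0.2, 0.0)
        means = centred.reshape(2000, 20).mean(axis=1)
        expect = 0.05 + 0.95 / 20
        assert np.var(means, ddof=1) == pytest.approx(expect, rel=0.1)


class TestHomogeneousMerges:
    def test_zero_merges_leave_data_unchanged(self, base_design):
        data = generate_trial(base_design, seed=1)
        merged = apply_homogeneous_merges(data, MergeSpec("S1", k0=0, k1=0), seed=2)
        assert np.array_equal(merged.analysis_cluster, data.analysis_cluster)
        assert np.array_equal(merged.outcome, data.outcome)

    @pytest.mark.parametrize("k0, k1", [(1, 1), (5, 3), (20, 20)])
    def test_s1_changes_labels_only(self, base_design, k0, k1):
        data = generate_trial(base_design, seed=1)
        merged = apply_homogeneous_merges(data, MergeSpec("S1", k0=k0, k1=k1), seed=2)
        assert np.array_equal(merged.outcome, data.outcome)  # bit-identical
        for arm in (0, 1):
            assert merged.outcome[merged.orig_arm == arm].mean() == data.outcome[data.orig_arm == arm].mean()
        assert len(merged.merged_from) == k0 + k1

    def test_each_cluster_merges_at_most_once(self, base_design):
        data = generate_trial(base_design, seed=3)
        merged = apply_homogeneous_merges(data, MergeSpec("S1", k0=20, k1=20), seed=4)
        parents = [p for pair in merged.merged_from.values() for p in pair]
        assert len(parents) == len(set(parents)) == 80

    def test_pairs_are_within_arm(self, base_design):
        data = generate_trial(base_design, seed=3)
        merged = apply_homogeneous_merges(data, MergeSpec("S1", k0=7, k1=4), seed=5)
        for a, b in merged.merged_from.values():
            assert (a < 40) == (b < 40)

    def test_post_merge_sizes_match_closed_form_variance(self, base_design):
        for k0, k1 in [(1, 1), (2, 2), (5, 5), (10, 10)]:
            data = generate_trial(base_design, seed=6)
            merged = apply_homogeneous_merges(data, MergeSpec("S1", k0=k0, k1=k1), seed=7)
            sizes = merged.analysis_cluster_sizes()
            assert np.var(sizes, ddof=1) == pytest.approx(merged_size_variance(20, 80, k0 + k1), abs=1e-9)

    def test_s2_with_full_completion_is_s1(self, base_design):
        data = generate_trial(base_design, seed=8)
        s1 = apply_homogeneous_merges(data, MergeSpec("S1", k0=4, k1=4), seed=9)
        s2 = apply_homogeneous_merges(
            data, MergeSpec("S2", k0=4, k1=4, completer_fraction=1.0), seed=9
        )
        assert np.array_equal(s1.outcome, s2.outcome)
        assert np.array_equal(s1.analysis_cluster, s2.analysis_cluster)

    def test_s2_noncompleters_share_one_new_cluster_effect(self, base_design):
        # with negligible individual error, regenerated outcomes within a merged
        # cluster collapse onto mu_arm + u_new: one value per merged cluster
        d = dataclasses.replace(base_design, sigma_w2=1e-18)
        data = generate_trial(d, mu0=0.0, mu1=0.2, seed=10)
        merged = apply_homogeneous_merges(data, MergeSpec("S2", k0=3, k1=3), seed=11)
        for label in merged.merged_from:
            mask = (merged.analysis_cluster == label) & ~merged.completer
            assert mask.sum() == 20  # half of each 20-member parent
            assert np.ptp(merged.outcome[mask]) < 1e-6
        # completers kept their original outcomes
        keep = merged.completer
        assert np.array_equal(merged.outcome[keep], data.outcome[keep])

    def test_insufficient_clusters_rejected(self, base_design):
        data = generate_trial(base_design, seed=0)
        with pytest.raises(ValueError):
            apply_homogeneous_merges(data, MergeSpec("S1", k0=21, k1=0), seed=0)


class TestHeterogeneousMerges:
    def test_zero_merges_unchanged(self, base_design):
        data = generate_trial(base_design, seed=1)
        spec = MergeSpec("S3", k=0, strategy="drop_merged")
        merged = apply_heterogeneous_merges(data, spec, seed=2)
        assert np.array_equal(merged.outcome, data.outcome)
        assert not merged.merged_from

    def test_merged_cluster_holds_m_from_each_arm(self, base_design):
        data = generate_trial(base_design, seed=1)
        merged = apply_heterogeneous_merges(data, MergeSpec("S3", k=5, strategy="drop_merged"), seed=2)
        for label in merged.merged_from:
            mask = merged.analysis_cluster == label
            assert mask.sum() == 40
            assert (merged.orig_arm[mask] == 1).sum() == 20

    def test_s3_outcomes_untouched_and_mixed_mean(self, base_design):
        # a merged cluster averages the two arm means: expect (mu0+mu1)/2
        d = dataclasses.replace(base_design, c=400)
        data = generate_trial(d, mu0=0.0, mu1=0.2, seed=3)
        merged = apply_heterogeneous_merges(data, MergeSpec("S3", k=100, strategy="drop_merged"), seed=4)
        assert np.array_equal(merged.outcome, data.outcome)
        mask = merged.in_merged_cluster
        assert merged.outcome[mask].mean() == pytest.approx(0.1, abs=0.02)

    def test_s4_full_completion_is_s3(self, base_design):
        data = generate_trial(base_design, seed=5)
        s3 = apply_heterogeneous_merges(data, MergeSpec("S3", k=6, strategy="drop_merged"), seed=6)
        s4 = apply_heterogeneous_merges(
            data, MergeSpec("S4", k=6, strategy="drop_merged", completer_fraction=1.0), seed=6
        )
        assert np.array_equal(s3.outcome, s4.outcome)
        assert s3.merged_from == s4.merged_from

    @pytest.mark.parametrize("strategy, mu_expected", [("assign_control", 0.0), ("assign_intervention", 0.2)])
    def test_s4_noncompleters_follow_postmerge_arm_mean(self, base_design, strategy, mu_expected):
        d = dataclasses.replace(base_design, sigma_b2=1e-18, sigma_w2=1e-18)
        data = generate_trial(d, mu0=0.0, mu1=0.2, seed=7)
        merged = apply_heterogeneous_merges(data, MergeSpec("S4", k=5, strategy=strategy), seed=8)
        mask = ~merged.completer
        assert mask.sum() == 5 * 20
        assert np.allclose(merged.outcome[mask], mu_expected, atol=1e-6)

    def test_scenario_strategy_validation(self):
        with pytest.raises(ValueError):
            MergeSpec("S3", k=2, strategy="as_one_cluster")
        with pytest.raises(ValueError):
            MergeSpec("S9", k=2)


class TestBuildAnalysisSet:
    def test_no_merges_any_strategy_is_original(self, base_design):
        data = generate_trial(base_design, seed=0)
        for strategy in ("as_one_cluster", "drop_merged", "completers_only", "assign_control"):
            aset = build_analysis_set(data, strategy)
            assert aset.included.all()
            assert np.array_equal(aset.analysis_arm, data.orig_arm)
            assert np.array_equal(aset.analysis_cluster, data.orig_cluster)

    def test_drop_merged_counts(self, base_design):
        data = generate_trial(base_design, seed=1)
        merged = apply_heterogeneous_merges(data, MergeSpec("S3", k=5, strategy="drop_merged"), seed=2)
        aset = build_analysis_set(merged, "drop_merged")
        assert aset.included.sum() == (80 - 2 * 5) * 20
        assert aset.analysis_cluster_sizes().size == 70

    def test_assign_strategies_relabel_whole_merged_cluster(self, base_design):
        data = generate_trial(base_design, seed=1)
        merged = apply_heterogeneous_merges(data, MergeSpec("S3", k=3, strategy="assign_control"), seed=2)
        ctrl = build_analysis_set(merged, "assign_control")
        trt = build_analysis_set(merged, "assign_intervention")
        mask = merged.in_merged_cluster
        assert (ctrl.analysis_arm[mask] == 0).all()
        assert (trt.analysis_arm[mask] == 1).all()
        assert np.array_equal(ctrl.analysis_arm[~mask], data.orig_arm[~mask])

    def test_completers_only_count_on_small_instance(self):
        # c=6, m=4, one cross-arm merge, half completers: the merged pair
        # contributes 2+2 subjects, unmerged clusters all 4
        d = TrialDesign(delta=0.2, m=4, c=6)
        data = generate_trial(d, seed=3)
        merged = apply_heterogeneous_merges(
            data, MergeSpec("S4", k=1, strategy="completers_only", completer_fraction=0.5), seed=4
        )
        aset = build_analysis_set(merged, "completers_only")
        assert aset.included.sum() == 6 * 4 - 2 * 2
        # completers are analysed under their original labels
        assert np.array_equal(aset.analysis_cluster[aset.included], data.orig_cluster[aset.included])
        assert np.array_equal(aset.analysis_arm[aset.included], data.orig_arm[aset.included])

    def test_as_one_cluster_rejected_for_cross_arm_merges(self, base_design):
        data = generate_trial(base_design, seed=1)
        merged = apply_heterogeneous_merges(data, MergeSpec("S3", k=2, strategy="drop_merged"), seed=2)
        with pytest.raises(ValueError):
            build_analysis_set(merged, "as_one_cluster")


class TestSerialisation:
    def test_csv_round_trip(self, base_design, tmp_path):
        data = generate_trial(base_design, seed=11)
        merged = apply_heterogeneous_merges(data, MergeSpec("S4", k=3, strategy="drop_merged"), seed=12)
        aset = build_analysis_set(merged, "drop_merged")
        path = tmp_path / "trial.csv"
        aset.to_csv(path)
        back = type(aset).from_csv(path)
        assert np.array_equal(back.analysis_arm, aset.analysis_arm)
        assert np.allclose(back.outcome, aset.outcome)
        assert back.merged_from == aset.merged_from
        assert back.design == aset.design
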