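import numpy as np
import pytest

from visnet import LearningConfig, TrainingSchedule, build_network
from visnet.evaluation import (
    capacity_at_criterion,
    correlation_matrix,
    object_selectivity,
    replicate_statistics,
    response_matrix,
    weight_distribution_diagnostics,
)

from conftest import TINY_RETINA, tiny_specs


def brute_force_selectivity(corr, n_objects, n_views):
    """Literal evaluation of the selectivity formula by explicit loops."""
    c = np.clip(corr, 0.0, None)
    within = between = 0.0
    n = n_objects * n_views
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            if i // n_views == j // n_views:
                within += c[i, j]
            else:
                between += c[i, j]
    w_perfect = n_objects * n_views * (n_views - 1)
    return within / (w_perfect + between)


class TestResponseMatrix:
    def test_shape_and_row_identity(self, tiny_trained, tiny_stimuli, tiny_bank):
        rm = response_matrix(tiny_trained, tiny_stimuli, bank=tiny_bank)
        assert rm.shape == (6, 64)
        assert rm.min() >= 0.0 and rm.max() <= 1.0
        # duplicated stimulus rows produce identical responses
        import copy

        stim2 = copy.deepcopy(tiny_stimuli)
        stim2.images[0, 1] = stim2.images[0, 0]
        rm2 = response_matrix(tiny_trained, stim2, bank=tiny_bank)
        np.testing.assert_array_equal(rm2[0], rm2[1])

    def test_untrained_network_warns(self, tiny_network, tiny_stimuli, tiny_bank):
        with pytest.warns(UserWarning, match="not fully trained"):
            response_matrix(tiny_network, tiny_stimuli, bank=tiny_bank)


class TestCorrelationMatrix:
    def test_unit_diagonal_and_symmetry(self, rng):
        rm = rng.uniform(0, 1, (6, 40))
        corr = correlation_matrix(rm)
        np.testing.assert_allclose(np.diag(corr), 1.0)
        np.testing.assert_allclose(corr, corr.T, atol=1e-12)

    def test_one_hot_rows_near_zero_correlation(self):
        n = 100
        rm = np.zeros((3, n))
        for i in range(3):
            rm[i, i] = 1.0
        corr = correlation_matrix(rm)
        off = corr[~np.eye(3, dtype=bool)]
        # exactly -1/(n-1) from mean-centering of one-hot vectors
        np.testing.assert_allclose(off, -1.0 / (n - 1), atol=1e-12)

    def test_permutation_invariance(self, rng):
        rm = rng.uniform(0, 1, (5, 30))
        perm = rng.permutation(30)
        np.testing.assert_allclose(
            correlation_matrix(rm), correlation_matrix(rm[:, perm]), atol=1e-12
        )

    def test_zero_variance_row_convention(self):
        rm = np.vstack([np.full(10, 0.5), np.arange(10, dtype=float)])
        corr = correlation_matrix(rm)
        assert corr[0, 0] == 1.0
        assert corr[0, 1] == 0.0 and corr[1, 0] == 0.0

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError):
            correlation_matrix(np.ones((1, 5)))


class TestObjectSelectivity:
    def test_perfect_block_diagonal_is_one(self):
        n_obj, n_views = 3, 4
        corr = np.kron(np.eye(n_obj), np.ones((n_views, n_views)))
        assert object_selectivity(corr, n_obj, n_views) == pytest.approx(1.0)

    def test_no_correlation_is_zero(self):
        corr = np.eye(8)
        assert object_selectivity(corr, 2, 4) == 0.0

    def test_matches_brute_force_on_given_blocks(self):
        # 2 objects x 2 views, within off-diagonal 0.5, between 0.25
        corr = np.full((4, 4), 0.25)
        corr[:2, :2] = 0.5
        corr[2:, 2:] = 0.5
        np.fill_diagonal(corr, 1.0)
        s = object_selectivity(corr, 2, 2)
        assert s == pytest.approx(brute_force_selectivity(corr, 2, 2))
        assert s == pytest.approx((4 * 0.5) / (4 + 8 * 0.25))

    def test_matches_brute_force_on_random_matrices(self, rng):
        rm = rng.uniform(0, 1, (12, 50))
        corr = correlation_matrix(rm)
        assert object_selectivity(corr, 4, 3) == pytest.approx(
            brute_force_selectivity(corr, 4, 3)
        )

    def test_invariant_under_object_relabelling(self, rng):
        n_obj, n_views = 4, 3
        rm = rng.uniform(0, 1, (12, 30))
        corr = correlation_matrix(rm)
        s0 = object_selectivity(corr, n_obj, n_views)
        perm = rng.permutation(n_obj)
        idx = np.concatenate([np.arange(o * n_views, (o + 1) * n_views) for o in perm])
        s1 = object_selectivity(corr[np.ix_(idx, idx)], n_obj, n_views)
        assert s1 == pytest.approx(s0)

    def test_invariant_under_view_permutation_within_object(self, rng):
        n_obj, n_views = 3, 4
        rm = rng.uniform(0, 1, (12, 30))
        corr = correlation_matrix(rm)
        s0 = object_selectivity(corr, n_obj, n_views)
        idx = np.concatenate(
            [o * n_views + rng.permutation(n_views) for o in range(n_obj)]
        )
        s1 = object_selectivity(corr[np.ix_(idx, idx)], n_obj, n_views)
        assert s1 == pytest.approx(s0)

    def test_strictly_increases_when_between_correlation_drops(self):
        corr = np.full((4, 4), 0.3)
        corr[:2, :2] = 0.8
        corr[2:, 2:] = 0.8
        np.fill_diagonal(corr, 1.0)
        s_before = object_selectivity(corr, 2, 2)
        corr2 = corr.copy()
        corr2[0, 3] = corr2[3, 0] = 0.1
        assert object_selectivity(corr2, 2, 2) > s_before

    def test_negative_correlations_clipped(self):
        corr = np.eye(4)
        corr[0, 1] = corr[1, 0] = 0.5  # within object 0
        corr[0, 2] = corr[2, 0] = -0.9  # negative between-object correlation
        clipped = object_selectivity(corr, 2, 2)
        assert clipped == pytest.approx(1.0 / 4.0)  # negatives drop out of B
        # switchable: negatives then shrink the denominator
        unclipped = object_selectivity(corr, 2, 2, clip_negative=False)
        assert unclipped > clipped

    def test_single_view_rejected(self):
        with pytest.raises(ValueError, match="n_views"):
            object_selectivity(np.eye(3), 3, 1)

    def test_wrong_shape_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            object_selectivity(np.eye(5), 2, 2)


class TestCapacityReadout:
    def test_threshold_scan_example(self):
        assert capacity_at_criterion([10, 20, 40], [0.9, 0.7, 0.5], 0.6) == 20

    def test_single_passing_count(self):
        assert capacity_at_criterion([5], [0.8], 0.6) == 5

    def test_all_failing(self):
        assert capacity_at_criterion([5, 10], [0.4, 0.3], 0.6) == 0

    def test_counts_after_first_failure_ignored(self):
        # load-until-failure: a later rebound does not extend capacity
        assert capacity_at_criterion([2, 3, 4], [0.9, 0.5, 0.9], 0.6) == 2

    def test_unsorted_counts_rejected(self):
        with pytest.raises(ValueError):
            capacity_at_criterion([10, 5], [0.9, 0.9], 0.6)


class TestReplicateStatistics:
    @pytest.fixture(scope="class")
    def tiny_replicates(self, tiny_stimuli, tiny_bank):
        summary, pairwise, raw = replicate_statistics(
            tiny_specs(),
            tiny_stimuli,
            {
                "competitive_standard": LearningConfig(rule="competitive_standard"),
                "oja": LearningConfig(rule="oja"),
            },
            TrainingSchedule(epochs_per_layer=1, rng_seed=0),
            seeds=[0, 0, 1],
            bank=tiny_bank,
        )
        return summary, pairwise, raw

    def test_summary_table_structure(self, tiny_replicates):
        summary, pairwise, raw = tiny_replicates
        assert set(summary["condition"]) == {"competitive_standard", "oja"}
        assert (summary["n"] == 3).all()
        assert len(pairwise) == 1
        assert pairwise.loc[0, "df"] == 4

    def test_identical_seeds_give_identical_runs(self, tiny_replicates):
        _summary, _pairwise, raw = tiny_replicates
        for vals in raw.values():
            assert vals[0] == vals[1]  # duplicated seed 0

    def test_mean_sd_formulas(self, tiny_replicates):
        summary, _pairwise, raw = tiny_replicates
        for _, row in summary.iterrows():
            vals = raw[row["condition"]]
            assert row["mean"] == pytest.approx(np.mean(vals))
            assert row["sd"] == pytest.approx(np.std(vals, ddof=1))

    def test_known_mean_sd_pair(self):
        vals = [0.9, 1.0]
        assert np.mean(vals) == pytest.approx(0.95)
        assert np.std(vals, ddof=1) == pytest.approx(np.sqrt(0.005))

    def test_too_few_seeds_rejected(self, tiny_stimuli, tiny_bank):
        with pytest.raises(ValueError):
            replicate_statistics(
                tiny_specs(), tiny_stimuli, {"oja": LearningConfig(rule="oja")},
                TrainingSchedule(epochs_per_layer=1), seeds=[0], bank=tiny_bank,
            )


class TestWeightDiagnostics:
    def test_lognormal_parameter_recovery(self):
        net = build_network(tiny_specs(), input_size=TINY_RETINA, input_channels=32, seed=0)
        rng = np.random.default_rng(0)
        net.weights[2] = rng.lognormal(mean=-3.0, sigma=0.5, size=net.weights[2].shape)
        diag = weight_distribution_diagnostics(net, 2)
        assert diag["lognormal"]["mu"] == pytest.approx(-3.0, abs=0.1)
        assert diag["lognormal"]["sigma"] == pytest.approx(0.5, abs=0.1)

    def test_zero_weights_excluded_from_fit(self):
        net = build_network(tiny_specs(), input_size=TINY_RETINA, input_channels=32, seed=0)
        rng = np.random.default_rng(1)
        w = rng.lognormal(-3, 0.5, net.weights[1].shape)
        w[:, ::2] = 0.0
        net.weights[1] = w
        diag = weight_distribution_diagnostics(net, 1)
        assert diag["lognormal"] is not None
        assert diag["lognormal"]["mu"] == pytest.approx(-3.0, abs=0.15)

    def test_ceiling_reported_for_clipped_layer(self):
        specs = tiny_specs(max_weight=0.06)
        net = build_network(specs, input_size=TINY_RETINA, input_channels=32, seed=0)
        net.weights[0] = np.clip(net.weights[0], None, 0.06)
        diag = weight_distribution_diagnostics(net, 0)
        assert diag["max_weight_ceiling"] == 0.06
        assert net.weights[0].max() <= 0.06

    def test_degenerate_all_zero_weights(self):
        net = build_network(tiny_specs(), input_size=TINY_RETINA, input_channels=32, seed=0)
        net.weights[3] = np.zeros_like(net.weights[3])
        diag = weight_distribution_diagnostics(net, 3)
        assert diag["lognormal"] is None
        assert diag["near_max_fraction"] == 0.0
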