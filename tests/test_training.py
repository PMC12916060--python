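import numpy as np
import pytest

from visnet import (
    LearningConfig,
    TrainingSchedule,
    build_network,
    train_layer,
    train_network,
)
from visnet.evaluation import response_matrix
from visnet.training import precompute_filtered

from conftest import TINY_RETINA, tiny_specs


class TestSchedule:
    def test_object_blocked_order(self):
        sched = TrainingSchedule(epochs_per_layer=1, rng_seed=0)
        order = sched.presentation_order(3, 2, layer_index=0, epoch=0)
        assert len(order) == 6
        objects_seen = [o for o, _v in order]
        # all views of one object are consecutive: the object sequence has
        # exactly one run per object
        runs = [o for i, o in enumerate(objects_seen) if i == 0 or o != objects_seen[i - 1]]
        assert sorted(runs) == [0, 1, 2] and len(runs) == 3
        # every (object, view) pair appears exactly once
        assert sorted(order) == [(o, v) for o in range(3) for v in range(2)]

    def test_order_deterministic_per_epoch(self):
        sched = TrainingSchedule(epochs_per_layer=2, rng_seed=7)
        assert sched.presentation_order(4, 3, 1, 0) == sched.presentation_order(4, 3, 1, 0)
        assert sched.presentation_order(4, 3, 1, 0) != sched.presentation_order(4, 3, 1, 1)

    def test_per_layer_epoch_counts(self):
        sched = TrainingSchedule(epochs_per_layer=(5, 4, 3, 2))
        assert [sched.epochs(l) for l in range(4)] == [5, 4, 3, 2]


class TestTrainLayer:
    def test_zero_learning_rate_leaves_weights_bit_identical(
        self, tiny_stimuli, tiny_bank
    ):
        net = build_network(tiny_specs(), input_size=TINY_RETINA, input_channels=32, seed=0)
        before = [w.copy() for w in net.weights]
        sched = TrainingSchedule(epochs_per_layer=1, rng_seed=0)
        cfg = LearningConfig(learning_rate=0.0)
        train_layer(net, 0, tiny_stimuli, sched, cfg, bank=tiny_bank)
        for a, b in zip(net.weights, before):
            assert np.array_equal(a, b)

    def test_lower_layers_frozen(self, tiny_stimuli, tiny_bank):
        net = build_network(tiny_specs(), input_size=TINY_RETINA, input_channels=32, seed=0)
        sched = TrainingSchedule(epochs_per_layer=1, rng_seed=0)
        cfg = LearningConfig(learning_rate=0.5)
        train_layer(net, 0, tiny_stimuli, sched, cfg, bank=tiny_bank)
        frozen = [w.copy() for w in net.weights]
        train_layer(net, 1, tiny_stimuli, sched, cfg, bank=tiny_bank)
        assert np.array_equal(net.weights[0], frozen[0])
        assert np.array_equal(net.weights[2], frozen[2])
        assert np.array_equal(net.weights[3], frozen[3])
        assert not np.array_equal(net.weights[1], frozen[1])

    def test_untrained_lower_layer_rejected(self, tiny_stimuli, tiny_bank):
        net = build_network(tiny_specs(), input_size=TINY_RETINA, input_channels=32, seed=0)
        sched = TrainingSchedule(epochs_per_layer=1, rng_seed=0)
        with pytest.raises(RuntimeError, match="trained first"):
            train_layer(net, 2, tiny_stimuli, sched, LearningConfig(), bank=tiny_bank)

    def test_layer_index_out_of_range(self, tiny_stimuli, tiny_bank):
        net = build_network(tiny_specs(), input_size=TINY_RETINA, input_channels=32, seed=0)
        sched = TrainingSchedule(epochs_per_layer=1)
        with pytest.raises(IndexError):
            train_layer(net, 4, tiny_stimuli, sched, LearningConfig(), bank=tiny_bank)

    def test_presentation_log(self, tiny_stimuli, tiny_bank):
        net = build_network(tiny_specs(), input_size=TINY_RETINA, input_channels=32, seed=0)
        sched = TrainingSchedule(epochs_per_layer=1, rng_seed=0)
        log = []
        train_layer(
            net, 0, tiny_stimuli, sched, LearningConfig(), bank=tiny_bank,
            presentation_log=log,
        )
        assert len(log) == 6  # 3 objects x 2 views x 1 epoch
        assert all(e == 0 for e, _o, _v in log)

    def test_weights_bounded_under_competitive_rule(self, tiny_stimuli, tiny_bank):
        net = build_network(tiny_specs(), input_size=TINY_RETINA, input_channels=32, seed=1)
        sched = TrainingSchedule(epochs_per_layer=4, rng_seed=1)
        cfg = LearningConfig(rule="competitive_standard", learning_rate=0.9)
        train_network(net, tiny_stimuli, sched, cfg, bank=tiny_bank)
        for w in net.weights:
            assert w.min() >= 0.0 and w.max() <= 1.0


class TestTrainNetwork:
    def test_determinism_end_to_end(self, tiny_stimuli, tiny_bank):
        results = []
        for _ in range(2):
            net = build_network(
                tiny_specs(), input_size=TINY_RETINA, input_channels=32, seed=9
            )
            sched = TrainingSchedule(epochs_per_layer=2, rng_seed=9)
            train_network(net, tiny_stimuli, sched, LearningConfig(), bank=tiny_bank)
            results.append([w.copy() for w in net.weights])
        for a, b in zip(*results):
            assert np.array_equal(a, b)

    def test_rate_matrix_shape_contract(self, tiny_trained, tiny_stimuli, tiny_bank):
        rm = response_matrix(tiny_trained, tiny_stimuli, bank=tiny_bank)
        assert rm.shape == (6, 64)

    def test_clipped_layers_respect_ceiling(self, tiny_stimuli, tiny_bank):
        from dataclasses import replace

        specs = tiny_specs(max_weight=0.2)
        specs[3] = replace(specs[3], max_weight=None)
        net = build_network(specs, input_size=TINY_RETINA, input_channels=32, seed=2)
        sched = TrainingSchedule(epochs_per_layer=3, rng_seed=2)
        cfg = LearningConfig(rule="competitive_standard", learning_rate=0.8)
        train_network(net, tiny_stimuli, sched, cfg, bank=tiny_bank)
        for w in net.weights[:3]:
            assert w.max() <= 0.2 + 1e-12

    def test_filtered_cache_reused(self, tiny_stimuli, tiny_bank):
        # passing a precomputed Gabor cache gives identical training results
        filtered = precompute_filtered(tiny_stimuli, tiny_bank)
        nets = []
        for f in (None, filtered):
            net = build_network(
                tiny_specs(), input_size=TINY_RETINA, input_channels=32, seed=4
            )
            sched = TrainingSchedule(epochs_per_layer=1, rng_seed=4)
            for l in range(4):
                train_layer(
                    net, l, tiny_stimuli, sched, LearningConfig(),
                    filtered=f, bank=tiny_bank,
                )
            nets.append(net)
        for a, b in zip(nets[0].weights, nets[1].weights):
            np.testing.assert_allclose(a, b, atol=1e-12)
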