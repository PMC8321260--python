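"""U-Net construction, parameter accounting, and layer-freezing transfer."""

import numpy as np
import pytest

from metaseg.segmodel import (
    UNet,
    UNetSpec,
    build_unet,
    count_parameters,
    effective_lr,
    fine_tune_layer_freezing,
    make_freeze_plan,
    run_freeze_stage,
    train_supervised,
)
from metaseg.synthetic_tasks import generate_pool, three_tissue_sources


def small_examples(n=8, size=16):
    spec = three_tissue_sources()[0]
    from metaseg.synthetic_tasks import generate_example

    rng = np.random.default_rng(3)
    return [generate_example(spec, rng, size=size) for _ in range(n)]


class TestBuild:
    def test_forward_shape_and_normalization(self, tiny_unet, rng):
        x = rng.random((3, 1, 32, 32), dtype=np.float32)
        p = tiny_unet.forward(x)
        assert p.shape == (3, 2, 32, 32)
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-5)
        assert p.min() >= 0.0

    def test_sigmoid_head_also_normalized(self, rng):
        spec = UNetSpec(n_down_blocks=2, base_channels=4, input_size=(16, 16), sigmoid_head=True)
        net = UNet(spec, 0)
        p = net.forward(rng.random((2, 1, 16, 16), dtype=np.float32))
        assert p.shape == (2, 2, 16, 16)
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-6)

    def test_seeded_builds_identical(self):
        a = build_unet(UNetSpec.tiny(), np.random.default_rng(5))
        b = build_unet(UNetSpec.tiny(), np.random.default_rng(5))
        assert np.array_equal(a.get_flat(), b.get_flat())

    def test_indivisible_input_size_rejected(self):
        with pytest.raises(ValueError):
            UNetSpec(n_down_blocks=4, input_size=(100, 100))

    def test_flat_roundtrip(self, tiny_unet, rng):
        theta = rng.standard_normal(tiny_unet.n_params).astype(np.float32)
        tiny_unet.set_flat(theta)
        assert np.array_equal(tiny_unet.get_flat(), theta)


class TestParameterCount:
    def test_single_conv_layer(self):
        from metaseg.segmodel.layers import Conv2d

        layer = Conv2d(1, 1, 3, np.random.default_rng(0))
        assert layer.n_params() == 10  # 9 weights + 1 bias

    def test_hand_enumerated_tiny_configuration(self):
        # n_down=1, base=2: widths (2,), bottleneck 4, softmax 2-class head.
        spec = UNetSpec(n_down_blocks=1, base_channels=2, input_size=(16, 16))
        net = UNet(spec, 0)
        conv = lambda ci, co: 9 * ci * co + co  # kernel + bias
        bn = lambda c: 2 * c
        up = lambda ci, co: 4 * ci * co + co
        expected = (
            conv(1, 2) + bn(2) + conv(2, 2) + bn(2)        # encoder block
            + conv(2, 4) + bn(4) + conv(4, 4) + bn(4)      # bottleneck
            + up(4, 2)                                      # transposed conv
            + conv(4, 2) + bn(2) + conv(2, 2) + bn(2)      # decoder block
            + (1 * 1 * 2 * 2 + 2)                           # 1x1 head
        )
        assert count_parameters(net) == expected

    def test_count_invariant_to_input_size(self):
        a = UNet(UNetSpec(n_down_blocks=2, base_channels=8, input_size=(32, 32)), 0)
        b = UNet(UNetSpec(n_down_blocks=2, base_channels=8, input_size=(64, 64)), 0)
        assert a.count_parameters() == b.count_parameters()

    def test_reference_configuration_total(self):
        net = UNet(UNetSpec.reference(), 0)
        assert net.count_parameters() == 4_320_609


class TestFreezePlan:
    def test_depth_two_stage_schedule(self):
        plan = make_freeze_plan(2, n_epochs_per_stage=10)
        assert [set(s.frozen_blocks) for s in plan.stages] == [{1, 2}, {1}, set()]
        assert [s.learning_rate for s in plan.stages] == [1e-3, 1e-3, 1e-4]
        assert [s.decay_rate for s in plan.stages] == [0.0, 0.0077, 0.0]

    def test_depth_one_schedule(self):
        plan = make_freeze_plan(1)
        assert [set(s.frozen_blocks) for s in plan.stages] == [{1}, set()]
        assert [s.learning_rate for s in plan.stages] == [1e-3, 1e-4]
        assert all(s.decay_rate == 0.0 for s in plan.stages)

    def test_depth_zero_degenerate(self):
        plan = make_freeze_plan(0)
        assert len(plan) == 1
        assert plan.stages[0].frozen_blocks == frozenset()
        assert plan.stages[0].learning_rate == 1e-4

    @pytest.mark.parametrize("depth", [0, 1, 2, 3])
    def test_stage_count_and_final_stage(self, depth):
        plan = make_freeze_plan(depth)
        assert len(plan) == depth + 1
        assert plan.stages[-1].frozen_blocks == frozenset()

    def test_depth_exceeding_encoder(self):
        with pytest.raises(ValueError):
            make_freeze_plan(5, n_down_blocks=4)

    def test_inverse_time_decay_law(self):
        for e in range(5):
            assert effective_lr(1e-3, 0.0077, e) == pytest.approx(1e-3 / (1 + 0.0077 * e))


class TestFreezingContract:
    def test_frozen_blocks_bitwise_unchanged_per_stage(self):
        spec = UNetSpec(n_down_blocks=2, base_channels=4, input_size=(16, 16))
        net = UNet(spec, np.random.default_rng(0))
        data = small_examples(8, 16)
        plan = make_freeze_plan(2, n_epochs_per_stage=2, n_down_blocks=2)
        rng = np.random.default_rng(1)
        for stage in plan.stages:
            before = net.get_flat()
            run_freeze_stage(net, stage, data, rng, batch_size=4)
            after = net.get_flat()
            for b in stage.frozen_blocks:
                for a_, z_ in net.block_param_slices(b):
                    assert np.array_equal(before[a_:z_], after[a_:z_])
            # and at least something else moved
            assert not np.array_equal(before, after)

    def test_frozen_bn_running_stats_pinned(self):
        spec = UNetSpec(n_down_blocks=2, base_channels=4, input_size=(16, 16))
        net = UNet(spec, np.random.default_rng(0))
        data = small_examples(6, 16)
        bn = net.enc_blocks[0].bn1
        net.set_frozen_blocks({1})
        mean_before = bn.running_mean.copy()
        train_supervised(net, data, n_epochs=1, lr=1e-3, rng=np.random.default_rng(0), batch_size=3)
        assert np.array_equal(bn.running_mean, mean_before)
        net.set_frozen_blocks(set())
        train_supervised(net, data, n_epochs=1, lr=1e-3, rng=np.random.default_rng(0), batch_size=3)
        assert not np.array_equal(bn.running_mean, mean_before)

    def test_all_frozen_encoder_still_trains_decoder(self):
        spec = UNetSpec(n_down_blocks=2, base_channels=4, input_size=(16, 16))
        net = UNet(spec, np.random.default_rng(0))
        data = small_examples(4, 16)
        net.set_frozen_blocks({1, 2})
        before = net.get_flat()
        train_supervised(net, data, n_epochs=1, lr=1e-3, rng=np.random.default_rng(0), batch_size=4)
        after = net.get_flat()
        enc = np.zeros(net.n_params, dtype=bool)
        for b in (1, 2):
            for a_, z_ in net.block_param_slices(b):
                enc[a_:z_] = True
        assert np.array_equal(before[enc], after[enc])
        assert not np.array_equal(before[~enc], after[~enc])

    def test_fine_tune_deterministic(self):
        spec = UNetSpec(n_down_blocks=2, base_channels=4, input_size=(16, 16))
        data = small_examples(6, 16)
        plan = make_freeze_plan(1, n_epochs_per_stage=2, n_down_blocks=2)
        outs = []
        for _ in range(2):
            net = UNet(spec, np.random.default_rng(0))
            fine_tune_layer_freezing(net, plan, data, np.random.default_rng(4), batch_size=3)
            outs.append(net.get_flat())
        assert np.array_equal(outs[0], outs[1])

    def test_logged_learning_rates_follow_decay(self):
        spec = UNetSpec(n_down_blocks=1, base_channels=2, input_size=(16, 16))
        net = UNet(spec, np.random.default_rng(0))
        data = small_examples(4, 16)
        hist = train_supervised(net, data, n_epochs=4, lr=1e-3,
                                rng=np.random.default_rng(0), decay=0.0077)
        assert hist["lr"] == [pytest.approx(1e-3 / (1 + 0.0077 * e)) for e in range(4)]


class TestWeightedLoss:
    def test_unit_weights_match_unweighted(self, tiny_unet, rng):
        from metaseg.metrics import one_hot

        x = rng.random((2, 1, 32, 32), dtype=np.float32)
        lab = (rng.random((2, 32, 32)) > 0.8).astype(int)
        y = np.stack([one_hot(m, 2) for m in lab])
        l0, g0 = tiny_unet.loss_and_grad_flat(x, y)
        l1, g1 = tiny_unet.loss_and_grad_flat(x, y, class_weights=(1.0, 1.0))
        assert l1 == pytest.approx(l0, rel=1e-6)
        assert np.allclose(g0, g1, atol=1e-6)

    def test_background_only_weight_ignores_foreground_pixels(self, tiny_unet, rng):
        from metaseg.metrics import one_hot

        x = rng.random((1, 1, 32, 32), dtype=np.float32)
        lab = (rng.random((1, 32, 32)) > 0.8).astype(int)
        y = np.stack([one_hot(m, 2) for m in lab])
        l_w, _ = tiny_unet.loss_and_grad_flat(x, y, class_weights=(1.0, 0.0))
        # equals the unweighted loss computed with foreground terms removed
        probs = tiny_unet.forward(x, train=True, update_bn_stats=False)
        manual = -np.sum(y[:, 0] * np.log(np.clip(probs[:, 0], 1e-7, 1.0)))
        assert l_w == pytest.approx(float(manual), rel=1e-5)


class TestBNCalibration:
    def test_running_stats_match_data_after_calibration(self):
        from metaseg.segmodel import calibrate_bn_stats

        spec = UNetSpec(n_down_blocks=2, base_channels=4, input_size=(16, 16))
        net = UNet(spec, np.random.default_rng(0))
        data = small_examples(12, 16)
        bn = net.enc_blocks[0].bn1
        assert np.allclose(bn.running_mean, 0.0)  # stale init moments
        calibrate_bn_stats(net, data, np.random.default_rng(1), n_passes=20, batch_size=6)
        x = np.stack([ex.image for ex in data])
        # first-layer batch stats over the whole set should be close to the
        # calibrated running stats
        h = net.enc_blocks[0].conv1.forward(
            np.ascontiguousarray(x[:, None].transpose(0, 2, 3, 1).astype(np.float32))
        )
        assert np.allclose(h.mean(axis=(0, 1, 2)), bn.running_mean, atol=0.05)

    def test_calibration_shrinks_train_eval_gap(self):
        from metaseg.segmodel import calibrate_bn_stats

        spec = UNetSpec(n_down_blocks=2, base_channels=4, input_size=(16, 16))
        net = UNet(spec, np.random.default_rng(2))
        data = small_examples(12, 16)
        x = np.stack([ex.image for ex in data])

        def gap():
            p_train = net.forward(x, train=True, update_bn_stats=False)
            p_eval = net.forward(x, train=False)
            return float(np.abs(p_train - p_eval).mean())

        stale = gap()
        calibrate_bn_stats(net, data, np.random.default_rng(3), n_passes=20, batch_size=12)
        calibrated = gap()
        assert calibrated < 0.5 * stale


class TestTranslationEquivariance:
    def test_periodic_shift_matches_on_interior(self):
        # eval mode (fresh BN stats are input-independent); shift by the full
        # down-sampling factor; compare away from the padded borders
        spec = UNetSpec(n_down_blocks=2, base_channels=4, input_size=(64, 64))
        net = UNet(spec, np.random.default_rng(0))
        rng = np.random.default_rng(1)
        x = rng.random((1, 1, 64, 64), dtype=np.float32)
        s = 4  # 2 ** n_down_blocks
        y1 = net.forward(x)
        y2 = net.forward(np.roll(x, s, axis=2))
        y1s = np.roll(y1, s, axis=2)
        m = 24
        assert np.allclose(y2[..., m:-m, m:-m], y1s[..., m:-m, m:-m], atol=1e-3)
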