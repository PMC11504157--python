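"""U-Net architecture, Dice loss, schedule, training loop, inference."""

import numpy as np
import pytest

import tkvnet.segmentation as seg
from tkvnet.dataset import AugmentationParams, LabeledPair
from tkvnet.evaluation import ConfusionCounts, dsc
from tkvnet.geometry_io import SeriesGeometry, SliceStack
from tkvnet.segmentation import (LRSchedule, TrainConfig, UNetConfig, build_unet,
                                 dice_loss, load_checkpoint, lr_at_step,
                                 predict_stack, save_checkpoint, train)


class TestBuildUnet:
    @pytest.mark.parametrize("depth,base", [(1, 4), (2, 8), (3, 4)])
    def test_output_shape_and_sigmoid_range(self, depth, base):
        model = build_unet(UNetConfig(depth=depth, base_filters=base,
                                      input_size=32, seed=0))
        x = np.random.default_rng(0).random((2, 1, 32, 32))
        out = model.forward(x)
        assert out.shape == (2, 1, 32, 32)
        assert np.all(out > 0.0) and np.all(out < 1.0)

    def test_parameter_count_matches_closed_form(self):
        # depth 1, base 4: enc(1->4, 4->4), bottleneck(4->8, 8->8),
        # up-conv(8->4, 2x2), dec(8->4, 4->4), head(4->1, 1x1)
        def conv3(cin, cout):
            return cin * 9 * cout + cout

        expected = (conv3(1, 4) + conv3(4, 4)
                    + conv3(4, 8) + conv3(8, 8)
                    + (2 * 2 * 8 * 4 + 4)
                    + conv3(8, 4) + conv3(4, 4)
                    + (4 * 1 + 1))
        model = build_unet(UNetConfig(depth=1, base_filters=4, input_size=16))
        assert model.n_parameters() == expected == 1645

    def test_excessive_depth_rejected(self):
        with pytest.raises(ValueError):
            UNetConfig(depth=9, input_size=256)

    def test_gradients_match_finite_differences(self):
        cfg = UNetConfig(depth=1, base_filters=2, input_size=8, seed=3,
                         dropout_rate=0.0)
        model = build_unet(cfg)
        rng = np.random.default_rng(0)
        x = rng.random((2, 1, 8, 8)).astype(np.float32)
        t = (rng.random((2, 1, 8, 8)) > 0.5).astype(np.float32)
        probs = model.forward(x)
        _, dp = seg._soft_dice_batch(probs, t)
        grads = model.backward(dp)
        params = model.parameters()
        eps = 1e-3
        for pi in (0, 3, len(params) // 2, len(params) - 1):
            p = params[pi]
            idx = tuple(0 for _ in p.shape)
            orig = p[idx]
            p[idx] = orig + eps
            l_plus, _ = seg._soft_dice_batch(model.forward(x), t)
            p[idx] = orig - eps
            l_minus, _ = seg._soft_dice_batch(model.forward(x), t)
            p[idx] = orig
            numeric = (l_plus - l_minus) / (2 * eps)
            assert grads[pi][idx] == pytest.approx(numeric, abs=2e-3)


class TestDiceLoss:
    def test_perfect_overlap_near_zero(self):
        t = (np.random.default_rng(0).random((16, 16)) > 0.5).astype(float)
        assert dice_loss(t, t) < 1e-5

    def test_disjoint_near_one(self):
        a = np.zeros((8, 8))
        a[:4] = 1
        b = np.zeros((8, 8))
        b[4:] = 1
        assert dice_loss(a, b) > 1 - 1e-5

    def test_partial_overlap_counts(self):
        truth = np.zeros((4, 4))
        truth[0, :4] = 1  # 4 pixels
        pred = truth.copy()
        pred[1, :2] = 1  # covers truth plus 2 extra
        assert dice_loss(pred, truth) == pytest.approx(0.2, abs=1e-6)

    def test_equals_one_minus_hard_dsc_for_binary(self):
        rng = np.random.default_rng(4)
        p = (rng.random((20, 20)) > 0.6).astype(float)
        t = (rng.random((20, 20)) > 0.6).astype(float)
        tp = int(np.sum((p == 1) & (t == 1)))
        fp = int(np.sum((p == 1) & (t == 0)))
        fn = int(np.sum((p == 0) & (t == 1)))
        assert dice_loss(p, t) == pytest.approx(
            1 - dsc(ConfusionCounts(tp, fp, fn)), abs=1e-6)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            dice_loss(np.zeros((4, 4)), np.zeros((5, 5)))


class TestLRSchedule:
    SCHED = LRSchedule(warmup_steps=50, peak_lr=2e-3, decay_rate=0.8,
                       decay_steps=25, floor=1e-5)

    def test_starts_at_floor(self):
        assert lr_at_step(0, self.SCHED) == pytest.approx(1e-5)

    def test_peak_at_warmup_junction(self):
        assert lr_at_step(50, self.SCHED) == pytest.approx(2e-3)
        # continuity: just before the junction the ramp is within one step's slope
        assert lr_at_step(49, self.SCHED) == pytest.approx(
            2e-3, abs=(2e-3 - 1e-5) / 50 + 1e-12)

    def test_one_decay_period(self):
        assert lr_at_step(75, self.SCHED) == pytest.approx(2e-3 * 0.8)

    def test_monotone_rampup_then_decay(self):
        lrs = [lr_at_step(s, self.SCHED) for s in range(200)]
        assert all(a <= b + 1e-15 for a, b in zip(lrs[:50], lrs[1:51]))
        assert all(a >= b for a, b in zip(lrs[50:], lrs[51:]))


def _tiny_pairs(n=6, size=16, seed=0):
    rng = np.random.default_rng(seed)
    pairs = []
    for k in range(n):
        mask = np.zeros((size, size), dtype=np.uint8)
        r, c = rng.integers(4, size - 4, 2)
        mask[r - 3:r + 3, c - 3:c + 3] = 1
        img = mask * 0.6 + rng.random((size, size)) * 0.1
        pairs.append(LabeledPair(np.clip(img, 0, 1), mask, "s", k))
    return pairs


class TestTrain:
    def test_constant_metric_with_patience_one_stops_at_epoch_two(self, monkeypatch):
        monkeypatch.setattr(seg, "_validation_dsc", lambda *a, **k: 0.5)
        pairs = _tiny_pairs()
        model = build_unet(UNetConfig(depth=1, base_filters=2, input_size=16))
        cfg = TrainConfig(batch_size=4, max_epochs=10, patience=1, seed=0)
        _, hist = train(model, pairs[:4], pairs[4:], cfg,
                        AugmentationParams(seed=0))
        assert hist.stopped_epoch == 2
        assert hist.best_epoch == 1

    def test_history_lengths_equal_stopped_epoch(self):
        pairs = _tiny_pairs()
        model = build_unet(UNetConfig(depth=1, base_filters=2, input_size=16))
        cfg = TrainConfig(batch_size=4, max_epochs=3, patience=5, seed=0)
        _, hist = train(model, pairs[:4], pairs[4:], cfg,
                        AugmentationParams(seed=0))
        assert len(hist.train_loss) == len(hist.val_dsc) == len(hist.lr) \
            == hist.stopped_epoch == 3

    def test_empty_sets_rejected(self):
        model = build_unet(UNetConfig(depth=1, base_filters=2, input_size=16))
        with pytest.raises(ValueError):
            train(model, [], _tiny_pairs(), TrainConfig())

    def test_seeded_runs_reproduce_first_epoch_loss(self):
        losses = []
        for _ in range(2):
            pairs = _tiny_pairs()
            model = build_unet(UNetConfig(depth=1, base_filters=2,
                                          input_size=16, seed=7))
            cfg = TrainConfig(batch_size=4, max_epochs=1, patience=5, seed=7)
            _, hist = train(model, pairs[:4], pairs[4:], cfg,
                            AugmentationParams(seed=7))
            losses.append(hist.train_loss[0])
        assert losses[0] == losses[1]

    def test_loss_decreases_on_easy_task(self):
        pairs = _tiny_pairs(n=8)
        model = build_unet(UNetConfig(depth=1, base_filters=4, input_size=16,
                                      seed=0))
        cfg = seg.small_data_train_config(max_epochs=20, seed=0)
        _, hist = train(model, pairs[:6], pairs[6:], cfg,
                        AugmentationParams(seed=0))
        assert min(hist.train_loss[-5:]) < hist.train_loss[0]


class TestPhantomEndToEnd:
    def test_validation_dice_reaches_080(self, trained_phantom):
        _, _, hist = trained_phantom
        assert hist.best_val_dsc >= 0.80
        assert hist.best_epoch <= hist.stopped_epoch

    def test_predict_stack_shapes_and_postprocessed_dice(self, trained_phantom):
        from tkvnet.postprocess import clean_mask

        model, case, _ = trained_phantom
        probs = predict_stack(model, case.stack)
        assert len(probs) == len(case.stack)
        for p in probs:
            assert p.shape == (case.spec.n_rows, case.spec.n_cols)
            assert p.min() >= 0.0 and p.max() <= 1.0
        dices = []
        for p, t in zip(probs, case.combined_masks):
            if not t.any():
                continue
            m = clean_mask(p)
            inter = np.logical_and(m, t).sum()
            dices.append(2 * inter / (m.sum() + t.sum()))
        assert np.mean(dices) >= 0.8

    def test_constant_input_gives_constant_output(self):
        model = build_unet(UNetConfig(depth=1, base_filters=2, input_size=16))
        geom = SeriesGeometry(1.0, 1.0, 5.0, None, 16, 16, "axial")
        stack = SliceStack([np.zeros((16, 16))] * 3, geom)
        probs = predict_stack(model, stack)
        for p in probs:
            assert np.ptp(p) < 1e-6


class TestCheckpoint:
    def test_round_trip_preserves_predictions(self, tmp_path):
        model = build_unet(UNetConfig(depth=1, base_filters=2, input_size=16,
                                      seed=2))
        x = np.random.default_rng(0).random((1, 1, 16, 16))
        before = model.forward(x)
        save_checkpoint(model, tmp_path / "ckpt.npz", TrainConfig())
        back = load_checkpoint(tmp_path / "ckpt.npz")
        np.testing.assert_allclose(back.forward(x), before, atol=1e-7)
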