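"""Soft Dice loss, network mechanics, training loop, checkpoint selection."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from drseg.nn import Adam, ModelConfig, UNet3D, softmax
from drseg.training import (
    Checkpoint,
    average_checkpoints,
    hard_dice_channels,
    one_hot_target,
    retain_model,
    select_checkpoint,
    soft_dice_loss,
    soft_dice_loss_grad,
    softmax_backward,
    train,
)
from drseg.generator import TrainingSample
from drseg.volumes import IntensityVolume, LabelVolume


def _one_hot(lab, k):
    t = np.zeros((k,) + lab.shape, dtype=np.float32)
    for c in range(k):
        t[c] = lab == c
    return t


class TestSoftDiceLoss:
    def test_one_hot_match_is_zero(self, rng):
        lab = rng.integers(0, 3, (6, 6, 6))
        t = _one_hot(lab, 3)
        assert soft_dice_loss(t, t) == pytest.approx(0.0)

    def test_disjoint_prediction_is_one(self):
        lab = np.zeros((4, 4, 4), int)
        lab[:2] = 1
        t = _one_hot(lab, 3)
        swapped = lab.copy()
        swapped[lab == 1] = 2
        swapped[lab == 0] = 1
        y = _one_hot(swapped, 3)
        # foreground channels of y never overlap those of t
        assert soft_dice_loss(y, t) == pytest.approx(1.0)

    def test_uniform_half_two_voxel_hand_case(self):
        # two voxels, two foreground labels, Y = 0.5 everywhere on foreground:
        # per-label term 2*0.5/(2*0.25+1) = 0.6667, loss = 0.3333
        t = np.zeros((3, 2, 1, 1), dtype=np.float32)
        t[1, 0] = 1.0
        t[2, 1] = 1.0
        y = np.zeros_like(t)
        y[1] = y[2] = 0.5
        assert soft_dice_loss(y, t) == pytest.approx(1 - 2 * 0.5 / 1.5, abs=1e-6)
        assert soft_dice_loss(y, t) == pytest.approx(0.3333, abs=1e-4)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            soft_dice_loss(np.zeros((2, 2, 2, 2)), np.zeros((2, 4, 4, 4)))

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_bounds_and_perfect_iff_one_hot(self, seed):
        rng = np.random.default_rng(seed)
        k = int(rng.integers(2, 5))
        lab = rng.integers(0, k, (4, 4, 4))
        t = _one_hot(lab, k)
        logits = rng.normal(0, 2, (k, 4, 4, 4)).astype(np.float32)
        y = softmax(logits)
        loss = soft_dice_loss(y, t)
        assert 0.0 <= loss <= 1.0
        if loss < 1e-12:
            np.testing.assert_allclose(y[1:], t[1:], atol=1e-6)

    def test_gradient_matches_finite_differences(self, rng):
        k = 3
        lab = rng.integers(0, k, (3, 3, 3))
        t = _one_hot(lab, k)
        y = softmax(rng.normal(0, 1, (k, 3, 3, 3)).astype(np.float64))
        loss, dy = soft_dice_loss_grad(y, t)
        eps = 1e-6
        for idx in [(1, 0, 0, 0), (2, 1, 2, 0), (1, 2, 2, 2)]:
            yp = y.copy(); yp[idx] += eps
            ym = y.copy(); ym[idx] -= eps
            num = (soft_dice_loss(yp, t) - soft_dice_loss(ym, t)) / (2 * eps)
            assert dy[idx] == pytest.approx(num, abs=1e-4)


class TestNetworkMechanics:
    def test_softmax_normalised(self, rng):
        y = softmax(rng.normal(0, 3, (4, 5, 5, 5)))
        np.testing.assert_allclose(y.sum(axis=0), 1.0, atol=1e-5)
        assert y.min() >= 0

    def test_forward_shape_and_determinism(self):
        net = UNet3D(1, 4, ModelConfig(), np.random.default_rng(0))
        x = np.random.default_rng(1).random((1, 16, 16, 16)).astype(np.float32)
        a = net.predict_proba(x)
        b = net.predict_proba(x)
        assert a.shape == (4, 16, 16, 16)
        np.testing.assert_array_equal(a, b)

    def test_indivisible_shape_rejected(self):
        net = UNet3D(1, 2, ModelConfig(n_levels=3), np.random.default_rng(0))
        with pytest.raises(ValueError, match="divisible"):
            net.forward(np.zeros((1, 10, 10, 10), np.float32))

    def test_weight_round_trip(self):
        rng = np.random.default_rng(2)
        net = UNet3D(1, 3, ModelConfig(n_levels=2, first_features=4), rng)
        w = net.get_weights()
        net2 = UNet3D(1, 3, ModelConfig(n_levels=2, first_features=4),
                      np.random.default_rng(99))
        net2.set_weights(w)
        x = rng.random((1, 8, 8, 8)).astype(np.float32)
        np.testing.assert_array_equal(net.predict_proba(x), net2.predict_proba(x))

    def test_adam_descends_on_quadratic(self):
        p = np.array([5.0, -3.0], dtype=np.float32)
        opt = Adam(learning_rate=0.1)
        for _ in range(500):
            g = 2 * p
            opt.step([(p, g)])
        assert np.abs(p).max() < 1e-2


class TestTrainingLoop:
    def test_single_step_single_log_row(self, small_corpus, desk_config):
        corpus = small_corpus[0]
        ckpts, log = train(corpus, desk_config, ModelConfig(n_levels=2,
                                                            first_features=4),
                           1, 1, np.random.default_rng(0))
        assert len(log) == 1 and len(ckpts) == 1
        assert 0.0 <= log["loss"].iloc[0] <= 1.0

    def test_reproducible_loss_trajectory(self, small_corpus, desk_config):
        corpus = small_corpus[0]
        mc = ModelConfig(n_levels=2, first_features=4)
        _, log1 = train(corpus, desk_config, mc, 5, 5, np.random.default_rng(3))
        _, log2 = train(corpus, desk_config, mc, 5, 5, np.random.default_rng(3))
        np.testing.assert_array_equal(log1["loss"], log2["loss"])

    def test_checkpoint_files_written(self, small_corpus, desk_config, tmp_path):
        corpus = small_corpus[0]
        ckpts, _ = train(corpus, desk_config, ModelConfig(n_levels=2,
                                                          first_features=4),
                         4, 2, np.random.default_rng(4), out_dir=tmp_path)
        assert (tmp_path / "training_log.csv").exists()
        assert len(list(tmp_path.glob("checkpoint_*.npz"))) == 2
        from drseg.inference import load_checkpoint

        back = load_checkpoint(ckpts[0].path)
        assert back.step == ckpts[0].step
        for a, b in zip(back.weights, ckpts[0].weights):
            np.testing.assert_array_equal(a, b)


class TestSelectCheckpoint:
    def _pair(self, lab):
        img = IntensityVolume(lab.data.astype(float) / max(lab.data.max(), 1))
        return TrainingSample(img, lab, {})

    def _const_ckpt(self, fill_label, seg_labels=(1, 2)):
        """Checkpoint whose network is biased towards one class everywhere."""
        net = UNet3D(1, len(seg_labels) + 1, ModelConfig(n_levels=1,
                                                         first_features=2),
                     np.random.default_rng(0))
        w = net.get_weights()
        for arr in w:
            arr[...] = 0
        w[-1][fill_label] = 10.0  # head bias
        return Checkpoint(0, w, ModelConfig(n_levels=1, first_features=2),
                          tuple(seg_labels))

    def test_single_checkpoint_returned(self, rng):
        lab = LabelVolume(rng.integers(0, 3, (8, 8, 8)))
        ckpt = self._const_ckpt(1)
        assert select_checkpoint([ckpt], [self._pair(lab)]) is ckpt

    def test_better_checkpoint_wins(self):
        lab = LabelVolume(np.ones((8, 8, 8), int))  # everything label 1
        good = self._const_ckpt(1)  # predicts channel 1 == label 1
        bad = self._const_ckpt(2)
        good.step, bad.step = 10, 20
        chosen = select_checkpoint([bad, good], [self._pair(lab)])
        assert chosen is good

    def test_tie_breaks_to_earliest(self, rng):
        lab = LabelVolume(np.zeros((8, 8, 8), int))
        a = self._const_ckpt(1)
        b = self._const_ckpt(1)
        a.step, b.step = 5, 10
        assert select_checkpoint([a, b], [self._pair(lab)]) is a

    def test_empty_inputs_rejected(self, rng):
        lab = LabelVolume(rng.integers(0, 2, (8, 8, 8)))
        with pytest.raises(ValueError):
            select_checkpoint([], [self._pair(lab)])
        with pytest.raises(ValueError):
            select_checkpoint([self._const_ckpt(1)], [])


class TestRetention:
    def _const_ckpt(self, fill_label, step=0, seg_labels=(1, 2)):
        net = UNet3D(1, len(seg_labels) + 1,
                     ModelConfig(n_levels=1, first_features=2),
                     np.random.default_rng(0))
        w = net.get_weights()
        for arr in w:
            arr[...] = 0
        w[-1][fill_label] = 10.0
        return Checkpoint(step, w, ModelConfig(n_levels=1, first_features=2),
                          tuple(seg_labels))

    def _pair(self, lab):
        img = IntensityVolume(lab.data.astype(float) / max(lab.data.max(), 1))
        return TrainingSample(img, lab, {})

    def test_average_checkpoints_means_weights(self):
        a = self._const_ckpt(1)
        b = self._const_ckpt(2)
        avg = average_checkpoints([a, b])
        np.testing.assert_allclose(avg.weights[-1][1:3], [5.0, 5.0])

    def test_tail_average_retained_when_validation_agrees(self):
        lab = LabelVolume(np.ones((8, 8, 8), int))
        ckpts = [self._const_ckpt(1, step=s) for s in (1, 2, 3)]
        retained = retain_model(ckpts, [self._pair(lab)])
        # all candidates score identically: the tail average is preferred
        np.testing.assert_allclose(retained.weights[-1][1], 10.0)
        assert retained is not ckpts[-1]

    def test_validation_vetoes_contaminated_tail(self):
        lab = LabelVolume(np.ones((8, 8, 8), int))
        good = self._const_ckpt(1, step=1)
        # a tail dominated by wrong-class weights drags the average under
        bad1 = self._const_ckpt(2, step=2)
        bad2 = self._const_ckpt(2, step=3)
        retained = retain_model([good, bad1, bad2], [self._pair(lab)])
        assert retained is good


def test_hard_dice_channels_hand_case():
    t = np.zeros((2, 2, 1, 1), dtype=np.float32)
    t[1, 0] = 1; t[0, 1] = 1
    y = t.copy()
    assert hard_dice_channels(y, t) == pytest.approx(1.0)
    y2 = np.zeros_like(t); y2[0] = 1  # predicts background everywhere
    assert hard_dice_channels(y2, t) == pytest.approx(0.0)


def test_one_hot_target_channel_order(rng):
    lab = LabelVolume(np.array([[[0, 3], [5, 3]]], dtype=int).reshape(1, 2, 2))
    t = one_hot_target(lab, (5, 3))
    assert t.shape == (3, 1, 2, 2)
    # channel order: background, then sorted labels (3 before 5)
    assert t[1, 0, 0, 1] == 1 and t[2, 0, 1, 0] == 1
    np.testing.assert_allclose(t.sum(axis=0), 1.0)
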