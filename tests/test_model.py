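"""Segmentation network: architecture, gradients, training behaviour,
whole-recording inference."""
import numpy as np
import pytest

from scgbeat._nn import weighted_cross_entropy
from scgbeat.datatypes import ScgRecording
from scgbeat.model import (
    SegmentBatch,
    TrainConfig,
    UNet1D,
    UNetConfig,
    build_network,
    load_model,
    predict_proba,
    save_model,
    train,
)


class TestArchitecture:
    def test_encoder_filter_counts_double_per_stage(self):
        cfg = UNetConfig(depth=5, init_filters=16)
        assert cfg.encoder_filters == [16, 32, 64, 128, 256]

    def test_forward_probabilities_normalised(self):
        cfg = UNetConfig(depth=3, init_filters=4, kernel_size=7, input_len=256)
        net = build_network(cfg, seed=0)
        p = net.predict(np.zeros((2, 3, 256), dtype=np.float32))
        assert p.shape == (2, 2, 256)
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-5)

    def test_input_len_divisibility_enforced(self):
        with pytest.raises(ValueError):
            UNetConfig(depth=5, input_len=1000)

    def test_parameter_count_matches_hand_count(self):
        # depth 1, 2 init filters, kernel 3, 3 input channels, 2 classes:
        # enc: conv(3->2,k3)=20, bn(2)=4, conv(2->2,k3)=14, bn=4
        # bridge: conv(2->4,k3)=28, bn(4)=8, conv(4->4,k3)=52, bn=8
        # up: convT(4->2,k2)=18
        # dec: conv(4->2,k3)=26, bn=4, conv(2->2,k3)=14, bn=4
        # head: conv(2->2,k1)=6
        cfg = UNetConfig(depth=1, init_filters=2, kernel_size=3, input_len=8)
        net = build_network(cfg, seed=0)
        expected = 20 + 4 + 14 + 4 + 28 + 8 + 52 + 8 + 18 + 26 + 4 + 14 + 4 + 6
        assert net.n_parameters() == expected

    def test_gradients_match_finite_differences(self):
        cfg = UNetConfig(depth=2, init_filters=3, kernel_size=5, input_len=16)
        net = UNet1D(cfg, seed=0, dtype=np.float64)
        rng = np.random.default_rng(1)
        x = rng.standard_normal((2, 3, 16))
        y = rng.integers(0, 2, (2, 16))
        w = np.array([1.0, 2.0])

        def loss_fn():
            return weighted_cross_entropy(
                net.forward_logits(x, training=True), y, w
            )

        loss, dl = loss_fn()
        net.backward(dl)
        eps = 1e-6
        for p in net.parameters():
            flat, grad = p["value"].ravel(), p["grad"].ravel()
            for i in rng.choice(flat.size, size=min(3, flat.size), replace=False):
                old = flat[i]
                flat[i] = old + eps
                lp, _ = loss_fn()
                flat[i] = old - eps
                lm, _ = loss_fn()
                flat[i] = old
                num = (lp - lm) / (2 * eps)
                assert abs(num - grad[i]) <= 1e-4 * max(1.0, abs(num))


def _toy_batches(n, seed, length=64, seps=16):
    """Tiny synthetic segmentation task: mark a window around each pulse."""
    rng = np.random.default_rng(seed)
    x = np.zeros((n, 3, length), dtype=np.float32)
    y = np.zeros((n, length), dtype=np.int64)
    for i in range(n):
        for c in range(0, length, seps):
            pos = c + int(rng.integers(4, seps - 4))
            x[i, :, pos] = 1.0
            y[i, pos - 2 : pos + 3] = 1
    return SegmentBatch(x, y)


class TestTraining:
    def test_plateau_schedule_drops_lr_then_stops(self):
        # a negligible learning rate cannot improve validation loss, so the
        # schedule must divide the rate by 10 every 2 stalled epochs and
        # stop once it falls below lr_min
        cfg = UNetConfig(depth=2, init_filters=2, kernel_size=3, input_len=64)
        net = build_network(cfg, seed=0)
        # 1e-12 steps vanish under float32 rounding, freezing the weights
        tc = TrainConfig(
            batch_size=8, lr_init=1e-12, lr_factor=0.1, lr_patience_epochs=2,
            lr_min=1e-14, max_epochs=50, class_weights=(1.0, 1.0), seed=0,
        )
        history = train(net, _toy_batches(8, 0), _toy_batches(4, 1), tc)
        lrs = [h["lr"] for h in history]
        assert lrs[:3] == [1e-12, 1e-12, 1e-12]  # best epoch + 2 stalled
        assert pytest.approx(1e-13) in lrs  # one factor-10 reduction applied
        assert len(history) < 50  # stopped well before max_epochs

    def test_lr_init_below_minimum_rejected(self):
        with pytest.raises(ValueError):
            TrainConfig(lr_init=1e-8, lr_min=1e-6)

    def test_loss_improves_on_learnable_task(self):
        cfg = UNetConfig(depth=2, init_filters=4, kernel_size=5, input_len=64)
        net = build_network(cfg, seed=0)
        tb = _toy_batches(40, 0)
        vb = _toy_batches(10, 1)
        tc = TrainConfig(batch_size=16, max_epochs=8, seed=0)
        history = train(net, tb, vb, tc)
        assert history[-1]["val_loss"] < history[0]["val_loss"]

    def test_seeded_training_is_deterministic(self):
        cfg = UNetConfig(depth=2, init_filters=2, kernel_size=3, input_len=64)
        losses = []
        for _ in range(2):
            net = build_network(cfg, seed=3)
            history = train(
                net, _toy_batches(8, 0), _toy_batches(4, 1),
                TrainConfig(batch_size=8, max_epochs=3, seed=3),
            )
            losses.append(history[-1]["val_loss"])
        assert abs(losses[0] - losses[1]) < 1e-6

    def test_overfit_capacity_on_noiseless_segments(self):
        # tiny network must reach >=0.99 per-sample accuracy on a small
        # noiseless training set (capacity sanity)
        cfg = UNetConfig(depth=3, init_filters=4, kernel_size=9, input_len=64)
        net = build_network(cfg, seed=0)
        tb = _toy_batches(50, 0)
        # longer plateau patience: the tiny validation set is noisy and the
        # default schedule would cut the learning rate before convergence
        tc = TrainConfig(
            batch_size=16, max_epochs=60, lr_patience_epochs=4, seed=0
        )
        train(net, tb, _toy_batches(8, 1), tc)
        pred = net.predict(tb.inputs).argmax(axis=1)
        acc = np.mean(pred == tb.targets)
        assert acc >= 0.99

    def test_empty_stream_rejected(self):
        cfg = UNetConfig(depth=2, init_filters=2, kernel_size=3, input_len=64)
        net = build_network(cfg, seed=0)
        empty = SegmentBatch(np.zeros((0, 3, 64)), np.zeros((0, 64)))
        with pytest.raises(ValueError):
            train(net, empty, _toy_batches(2, 1), TrainConfig(batch_size=4))


@pytest.fixture(scope="module")
def small_net():
    cfg = UNetConfig(depth=2, init_filters=2, kernel_size=3, input_len=64)
    return build_network(cfg, seed=0)


class TestWholeRecordingInference:
    def test_exact_window_single_tile(self, small_net):
        rec = ScgRecording(np.zeros((3, 64)), fs=200.0)
        mask = predict_proba(small_net, rec)
        assert mask.n_samples == 64

    def test_overlap_averaging_covers_recording(self, small_net):
        rec = ScgRecording(
            np.random.default_rng(0).standard_normal((3, 96)), fs=200.0
        )
        mask = predict_proba(small_net, rec)
        assert mask.n_samples == 96
        assert np.all(mask.values >= 0) and np.all(mask.values <= 1)

    def test_short_recording_reflect_padded(self, small_net):
        rec = ScgRecording(np.zeros((3, 40)), fs=200.0)
        mask = predict_proba(small_net, rec)
        assert mask.n_samples == 40

    def test_constant_input_gives_uniform_interior_profile(self, small_net):
        rec = ScgRecording(np.zeros((3, 128)), fs=200.0)
        mask = predict_proba(small_net, rec)
        interior = mask.values[16:-16]
        assert np.std(interior) < 0.05

    def test_checkpoint_round_trip(self, small_net, tmp_path):
        path = tmp_path / "model.npz"
        save_model(small_net, str(path))
        loaded = load_model(str(path))
        x = np.random.default_rng(0).standard_normal((1, 3, 64)).astype(np.float32)
        assert np.allclose(loaded.predict(x), small_net.predict(x), atol=1e-6)
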