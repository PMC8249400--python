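import numpy as np
import pytest

from orbitseg import nets
from orbitseg.nets.layers import BatchNorm2d, Conv2d, cross_entropy, softmax
from orbitseg.pipeline import build_stage1_dataset, build_stage2_dataset


def tiny_ring_task(n=10, size=32, seed=0):
    """Images with a bright ring; target = the ring pixels."""
    rng = np.random.default_rng(seed)
    xs, ys = [], []
    for _ in range(n):
        r0 = rng.uniform(6, 10)
        cy, cx = rng.uniform(12, 20, 2)
        rr, cc = np.mgrid[0:size, 0:size]
        rho = np.hypot(rr - cy, cc - cx)
        ring = np.abs(rho - r0) <= 1.5
        img = 0.2 + 0.7 * ring + rng.normal(0, 0.02, (size, size))
        xs.append(img)
        ys.append(ring.astype(np.int64))
    return np.stack(xs).astype(np.float32), np.stack(ys)


class TestArchitecture:
    @pytest.mark.parametrize("depth,size", [(4, 128), (3, 64), (2, 32)])
    def test_output_shape_two_class(self, depth, size):
        net = nets.build_unet(nets.UNetConfig(depth=depth, base_filters=4), seed=0)
        out = net.forward(np.zeros((1, size, size, 1), np.float32), train=False)
        assert out.shape == (1, size, size, 2)

    def test_indivisible_shape_rejected(self):
        net = nets.build_unet(nets.UNetConfig(depth=4, base_filters=4))
        with pytest.raises(ValueError, match="divisible"):
            net.forward(np.zeros((1, 100, 100, 1), np.float32))

    def test_rectangular_input_supported(self):
        # fully convolutional: works on any divisible size, e.g. half-images
        net = nets.build_unet(nets.UNetConfig(depth=3, base_filters=4))
        out = net.forward(np.zeros((2, 64, 32, 1), np.float32), train=False)
        assert out.shape == (2, 64, 32, 2)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            nets.UNetConfig(depth=0)
        with pytest.raises(ValueError):
            nets.UNetConfig(dropout_rate=1.0)


class TestGradients:
    def test_conv_backward_matches_finite_differences(self, rng):
        layer = Conv2d(3, 4, 3, rng)
        x = rng.normal(size=(2, 8, 8, 3)).astype(np.float32)
        out = layer.forward(x, train=True)
        r = rng.normal(size=out.shape).astype(np.float32)
        dx = layer.backward(r.copy())
        eps = 1e-3
        for _ in range(6):
            idx = tuple(rng.integers(0, s) for s in x.shape)
            xp, xm = x.copy(), x.copy()
            xp[idx] += eps
            xm[idx] -= eps
            num = float(((layer.forward(xp, True) - layer.forward(xm, True)) * r).sum()) / (2 * eps)
            assert num == pytest.approx(dx[idx], rel=0.02, abs=1e-3)

    def test_batchnorm_backward_matches_finite_differences(self, rng):
        layer = BatchNorm2d(3)
        x = rng.normal(size=(2, 6, 6, 3)).astype(np.float32)
        out = layer.forward(x, train=True)
        r = rng.normal(size=out.shape).astype(np.float32)
        dx = layer.backward(r.copy())
        eps = 1e-3
        for _ in range(6):
            idx = tuple(rng.integers(0, s) for s in x.shape)
            xp, xm = x.copy(), x.copy()
            xp[idx] += eps
            xm[idx] -= eps
            num = float(((layer.forward(xp, True) - layer.forward(xm, True)) * r).sum()) / (2 * eps)
            assert num == pytest.approx(dx[idx], rel=0.03, abs=2e-3)

    def test_softmax_and_cross_entropy(self, rng):
        logits = rng.normal(size=(2, 4, 4, 2)).astype(np.float32)
        p = softmax(logits)
        assert np.allclose(p.sum(axis=-1), 1.0, atol=1e-6)
        targets = rng.integers(0, 2, (2, 4, 4))
        loss, d = cross_entropy(logits, targets)
        assert loss > 0
        assert np.allclose(d.sum(axis=-1), 0.0, atol=1e-6)  # gradient rows sum to zero


class TestTraining:
    def test_one_epoch_returns_log_of_length_one(self):
        x, y = tiny_ring_task(8)
        cfg = nets.TrainConfig.stage1(epochs=1, batch_size=4)
        net = nets.build_unet(nets.UNetConfig(depth=2, base_filters=4), seed=0)
        tm = nets.train(net, (x[:6], y[:6]), (x[6:], y[6:]), cfg)
        assert len(tm.log) == 1
        assert tm.best_epoch == 0

    def test_loss_decreases_on_learnable_task(self):
        x, y = tiny_ring_task(12)
        cfg = nets.TrainConfig.stage2(epochs=12, batch_size=4)
        net = nets.build_unet(nets.UNetConfig(depth=2, base_filters=4, dropout_rate=0.2), seed=1)
        tm = nets.train(net, (x[:9], y[:9]), (x[9:], y[9:]), cfg)
        assert tm.log[-1]["train_loss"] < tm.log[0]["train_loss"]
        # checkpoint rule: stored epoch maximizes validation accuracy, with
        # ties broken by the lowest validation loss
        accs = np.array([row["val_acc"] for row in tm.log])
        losses = np.array([row["val_loss"] for row in tm.log])
        best = np.flatnonzero(accs == accs.max())
        assert tm.best_epoch == int(best[np.argmin(losses[best])])

    def test_trained_model_separates_boundary_from_background(self):
        x, y = tiny_ring_task(12, seed=3)
        cfg = nets.TrainConfig.stage2(epochs=15, batch_size=4)
        net = nets.build_unet(nets.UNetConfig(depth=2, base_filters=4, dropout_rate=0.0), seed=2)
        tm = nets.train(net, (x[:9], y[:9]), (x[9:], y[9:]), cfg)
        pm = nets.predict_map(tm, x[10])
        assert 0.0 <= pm.min() and pm.max() <= 1.0
        assert pm[y[10] == 1].mean() > pm[y[10] == 0].mean()

    def test_same_seed_identical_trajectories(self):
        x, y = tiny_ring_task(8)
        cfg = nets.TrainConfig.stage1(epochs=3, batch_size=4, seed=9)
        runs = []
        for _ in range(2):
            net = nets.build_unet(nets.UNetConfig(depth=2, base_filters=4), seed=5)
            tm = nets.train(net, (x[:6], y[:6]), (x[6:], y[6:]), cfg)
            runs.append([row["val_acc"] for row in tm.log])
        assert runs[0] == runs[1]

    def test_empty_validation_set_refused(self):
        x, y = tiny_ring_task(4)
        net = nets.build_unet(nets.UNetConfig(depth=2, base_filters=4))
        with pytest.raises(ValueError, match="validation"):
            nets.train(net, (x, y), (x[:0], y[:0]), nets.TrainConfig(epochs=1))

    def test_stage_recipes_match_contract(self):
        s1, s2 = nets.TrainConfig.stage1(), nets.TrainConfig.stage2()
        assert (s1.optimizer, s1.learning_rate, s1.epochs, s1.batch_size) == (
            "adam", 1e-3, 100, 128)
        assert (s2.optimizer, s2.learning_rate, s2.epochs, s2.batch_size) == (
            "sgd_momentum", 1e-2, 500, 128)
        assert s2.momentum == 0.9

    def test_save_load_roundtrip(self, tmp_path):
        x, y = tiny_ring_task(6)
        cfg = nets.TrainConfig.stage1(epochs=2, batch_size=4)
        net = nets.build_unet(nets.UNetConfig(depth=2, base_filters=4), seed=0)
        tm = nets.train(net, (x[:4], y[:4]), (x[4:], y[4:]), cfg, fold=3)
        nets.save_model(tm, tmp_path / "ck.npz")
        back = nets.load_model(tmp_path / "ck.npz")
        assert back.fold == 3 and back.best_epoch == tm.best_epoch
        assert np.allclose(nets.predict_map(back, x[0]), nets.predict_map(tm, x[0]))


def test_phantom_training_signal(ct_volume):
    """Stage datasets built from phantoms have learnable structure: the
    stage-1 target marks the orbit region, stage-2 the dilated boundary."""
    x1, y1 = build_stage1_dataset([ct_volume], "ct")
    assert x1.shape == (5, 128, 64) and y1.shape == x1.shape
    assert 0.01 < y1.mean() < 0.5
    x2, y2 = build_stage2_dataset([ct_volume], "ct", boundary_thickness=3)
    assert x2.shape == (5, 128, 128)
    assert 0.005 < y2.mean() < 0.2
    assert x1.min() >= 0 and x1.max() <= 1
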