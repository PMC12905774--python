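"""3D dense classifier: channel trace, forward contracts, training recipe,
serialization, occlusion maps, and gradient correctness of the autograd engine."""

import numpy as np
import pytest

from rsipipe.errors import ConfigurationError
from rsipipe.metrics import roc_auc
from rsipipe.nn import (
    DenseNet3d,
    DenseNetConfig,
    TrainConfig,
    channel_trace,
    load_classifier,
    lr_at_step,
    occlusion_sensitivity,
    predict_proba,
    save_classifier,
    train_classifier,
)
from rsipipe.nn import autograd as ag


def test_channel_trace_full_size_schedule():
    """The full-size configuration reproduces the published channel schedule."""
    assert channel_trace(DenseNetConfig.full()) == (64, 256, 128, 512, 256, 1024, 512, 1024)


def test_channel_trace_matches_hand_recurrence():
    cfg = DenseNetConfig.tiny()
    # independent recurrence oracle
    expected = []
    ch = cfg.init_features
    expected.append(ch)
    for i, layers in enumerate(cfg.block_layers):
        ch = ch + layers * cfg.growth_rate
        expected.append(ch)
        if i < 3:
            ch = int(ch * cfg.compression)
            expected.append(ch)
    assert channel_trace(cfg) == tuple(expected)
    # degenerate growth: constant except compression
    flat = DenseNetConfig(init_features=8, growth_rate=0, block_layers=(2, 2, 2, 2))
    assert channel_trace(flat) == (8, 8, 4, 4, 2, 2, 1, 1)


def test_forward_shapes_and_softmax(rng):
    model = DenseNet3d(DenseNetConfig.tiny(), seed=0)
    x = rng.standard_normal((2, 3, 8, 8, 6))
    logits = model(x)
    assert logits.data.shape == (2, 2)
    p = ag.softmax(logits.data)
    assert np.allclose(p.sum(axis=1), 1.0, atol=1e-6)
    with pytest.raises(ConfigurationError, match="channels|input"):
        model(rng.standard_normal((2, 5, 8, 8, 6)))


def test_scalar_fusion_sensitivity(rng):
    fused = DenseNet3d(DenseNetConfig.tiny(in_channels=5, scalar_fusion=True), seed=0)
    x = rng.standard_normal((2, 5, 8, 8, 6))
    fused.eval()
    out1 = fused(x, scalar=np.array([0.0, 0.0])).data
    out2 = fused(x, scalar=np.array([5.0, 5.0])).data
    assert not np.allclose(out1, out2)
    plain = DenseNet3d(DenseNetConfig.tiny(), seed=0)
    with pytest.raises(ConfigurationError, match="scalar"):
        plain(rng.standard_normal((1, 3, 8, 8, 6)), scalar=np.array([1.0]))
    with pytest.raises(ConfigurationError, match="scalar"):
        fused(x)


def test_lr_schedule_endpoints():
    assert lr_at_step(0, 100, 10, 1e-3) == 0.0
    assert lr_at_step(10, 100, 10, 1e-3) == pytest.approx(1e-3)
    assert lr_at_step(100, 100, 10, 1e-3) == pytest.approx(0.0, abs=1e-12)
    assert lr_at_step(99, 100, 10, 1e-3) < 1e-5


def _separable_set(rng, n=40, shape=(8, 8, 6)):
    """Volumes whose class-1 members carry a bright central blob."""
    y = np.array([0, 1] * (n // 2))
    x = rng.standard_normal((n, 3, *shape)) * 0.3
    blob = np.zeros(shape)
    blob[2:6, 2:6, 2:4] = 2.0
    for i in range(n):
        if y[i] == 1:
            x[i, 0] += blob
    return x.astype(np.float64), y


def test_tiny_model_overfits_separable_set(rng):
    x, y = _separable_set(rng)
    tcfg = TrainConfig(total_epochs=30, batch_size=8, seed=0, internal_val_fraction=0.1)
    trained = train_classifier(x, None, y, DenseNetConfig.tiny(), tcfg)
    p = predict_proba(trained, x)
    assert roc_auc(p, y) == 1.0
    assert 1 <= trained.best_epoch <= tcfg.total_epochs
    assert len(trained.history) == tcfg.total_epochs


def test_training_deterministic_under_seed(rng):
    x, y = _separable_set(rng, n=16)
    tcfg = TrainConfig(total_epochs=3, batch_size=8, seed=5)
    t1 = train_classifier(x, None, y, DenseNetConfig.tiny(), tcfg)
    t2 = train_classifier(x, None, y, DenseNetConfig.tiny(), tcfg)
    for (k1, p1), (_, p2) in zip(sorted(t1.model.state_dict().items()),
                                 sorted(t2.model.state_dict().items())):
        assert np.array_equal(p1, p2), k1
    assert t1.history.equals(t2.history)


def test_training_loss_mostly_decreasing(rng):
    """Full-batch training loss decreases in at least 90% of epoch steps."""
    fractions = []
    for seed in (0, 1, 2):
        g = np.random.default_rng(seed)
        x, y = _separable_set(g, n=24)
        tcfg = TrainConfig(total_epochs=10, batch_size=24, seed=seed)
        trained = train_classifier(x, None, y, DenseNetConfig.tiny(), tcfg)
        diffs = np.diff(trained.history["train_loss"].to_numpy())
        fractions.append(np.mean(diffs <= 1e-9))
    assert np.mean(fractions) >= 0.9, fractions


def test_single_class_training_errors(rng):
    x = rng.standard_normal((8, 3, 8, 8, 6))
    with pytest.raises(ConfigurationError, match="both classes"):
        train_classifier(x, None, np.zeros(8, dtype=int), DenseNetConfig.tiny(),
                         TrainConfig(total_epochs=1))


def test_save_load_identical_predictions(rng, tmp_path):
    x, y = _separable_set(rng, n=16)
    s = rng.standard_normal(16)
    tcfg = TrainConfig(total_epochs=2, batch_size=8, seed=1)
    trained = train_classifier(x[:, :3], s, y, DenseNetConfig.tiny(in_channels=3, scalar_fusion=True), tcfg)
    p1 = predict_proba(trained, x[:, :3], s)
    path = save_classifier(trained, tmp_path / "ckpt.npz")
    reloaded = load_classifier(path)
    p2 = predict_proba(reloaded, x[:, :3], s)
    assert np.allclose(p1, p2, atol=1e-12)
    assert reloaded.best_epoch == trained.best_epoch


def test_predict_equals_manual_softmax(rng):
    x, y = _separable_set(rng, n=12)
    tcfg = TrainConfig(total_epochs=1, batch_size=6, seed=2)
    trained = train_classifier(x, None, y, DenseNetConfig.tiny(), tcfg)
    p = predict_proba(trained, x)
    logits = trained.model(x).data
    manual = np.exp(logits[:, 1]) / np.exp(logits).sum(axis=1)
    assert np.allclose(p, manual, atol=1e-12)
    assert np.all((p >= 0) & (p <= 1))


def test_autograd_matches_finite_differences(rng):
    cfg = DenseNetConfig(in_channels=2, init_features=4, growth_rate=2,
                         block_layers=(1, 1, 1, 1), scalar_fusion=True,
                         fusion_width=3, preset="custom")
    model = DenseNet3d(cfg, seed=0)
    x = rng.standard_normal((2, 2, 6, 6, 4))
    s = rng.standard_normal(2)
    y = np.array([0, 1])

    def loss_value():
        model.train()
        return ag.softmax_cross_entropy(model(ag.Tensor(x), scalar=s), y)

    loss = loss_value()
    loss.backward()
    errs = []
    eps = 1e-5
    for p in model.parameters():
        for _ in range(2):
            idx = tuple(rng.integers(0, d) for d in p.data.shape)
            orig = p.data[idx]
            p.data[idx] = orig + eps
            lp = float(loss_value().data)
            p.data[idx] = orig - eps
            lm = float(loss_value().data)
            p.data[idx] = orig
            num = (lp - lm) / (2 * eps)
            errs.append(abs(num - p.grad[idx]) / max(1e-8, abs(num) + abs(p.grad[idx])))
    errs = np.asarray(errs)
    # median catches systematic backward bugs; stray ReLU-kink crossings in the
    # finite difference can inflate individual coordinates
    assert np.median(errs) < 1e-5
    assert errs.max() < 1e-2


def _trained_tiny(rng, scalar=False):
    x, y = _separable_set(rng, n=16)
    tcfg = TrainConfig(total_epochs=2, batch_size=8, seed=3)
    cfg = DenseNetConfig.tiny(in_channels=3, scalar_fusion=scalar)
    s = rng.standard_normal(16) if scalar else None
    return train_classifier(x, s, y, cfg, tcfg), x


def test_occlusion_zero_perturbation_and_shape(rng):
    trained, x = _trained_tiny(rng)
    const = np.full((3, 8, 8, 6), 1.7)
    m = occlusion_sensitivity(trained, const, patch_size=4, stride=2)
    assert m.shape == (8, 8, 6)
    assert np.allclose(m, 0.0, atol=1e-12)  # occluding with identical values
    with pytest.raises(ConfigurationError):
        occlusion_sensitivity(trained, x[0], patch_size=4, stride=0)
    with pytest.raises(ConfigurationError):
        occlusion_sensitivity(trained, x[0], patch_size=64)


def test_occlusion_single_patch_equals_direct_difference(rng):
    trained, x = _trained_tiny(rng)
    vol = x[1]
    m = occlusion_sensitivity(trained, vol, patch_size=(8, 8, 6), stride=8)
    base = predict_proba(trained, vol[None])[0]
    occ = vol.copy()
    occ[:] = vol.reshape(3, -1).mean(axis=1)[:, None, None, None]
    direct = base - predict_proba(trained, occ[None])[0]
    assert np.allclose(m, direct, atol=1e-12)
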