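import numpy as np
import pytest

from synrec.nn import (
    AdamW,
    ReduceLROnPlateau,
    TrainConfig,
    UNet,
    UNetConfig,
    build_unet,
    dice_loss_and_grad,
    load_checkpoint,
    predict_tiled,
    save_checkpoint,
    targets_from_labels,
    train_supervised,
)
from synrec.nn.train import TrainedModel


def test_feature_widths_and_downsample_factors():
    cfg = UNetConfig(dimensionality=3, levels=4, initial_features=32, feature_growth=2)
    assert cfg.feature_widths == [32, 64, 128, 256]
    aniso = UNetConfig(dimensionality=3, levels=4, anisotropic_first_downsample=True)
    assert aniso.downsample_factors == [(1, 2, 2), (2, 2, 2), (2, 2, 2)]
    assert aniso.divisor == (4, 8, 8)
    iso2d = UNetConfig(dimensionality=2, levels=4)
    assert iso2d.divisor == (8, 8)


def test_forward_shape_and_range_3d():
    cfg = UNetConfig(dimensionality=3, levels=3, initial_features=4, anisotropic_first_downsample=True)
    net = build_unet(cfg, seed=0)
    x = np.random.default_rng(0).normal(size=(1, 4, 16, 16, 1)).astype(np.float32)
    out = net.forward(x)
    assert out.shape == (1, 4, 16, 16, 2)
    assert out.min() >= 0.0 and out.max() <= 1.0


def test_indivisible_patch_rejected():
    net = build_unet(UNetConfig(dimensionality=2, levels=3, initial_features=4), seed=0)
    with pytest.raises(ValueError, match="divisible"):
        net.forward(np.zeros((1, 10, 12, 1), dtype=np.float32))


def test_backprop_matches_directional_derivative(rng):
    """Full-network analytic gradient agrees with a finite difference."""
    cfg = UNetConfig(dimensionality=2, levels=2, initial_features=3, convs_per_block=1)
    net = build_unet(cfg, seed=0)
    x = rng.normal(size=(2, 8, 8, 1)).astype(np.float32)
    t = (rng.uniform(size=(2, 8, 8, 2)) > 0.5).astype(np.float32)
    pred = net.forward(x)
    _, g = dice_loss_and_grad(pred, t)
    net.backward(g)
    grads = {k: v.copy() for k, v in net.gradients().items()}
    params = net.parameters()
    dirs = {k: rng.normal(size=v.shape).astype(np.float32) for k, v in params.items()}
    analytic = sum(float((grads[k] * dirs[k]).sum()) for k in params)
    eps = 3e-3
    for k in params:
        params[k] += eps * dirs[k]
    l1, _ = dice_loss_and_grad(net.forward(x), t)
    for k in params:
        params[k] -= 2 * eps * dirs[k]
    l2, _ = dice_loss_and_grad(net.forward(x), t)
    numeric = (l1 - l2) / (2 * eps)
    assert abs(numeric - analytic) / abs(analytic) < 0.05


def test_dice_loss_of_perfect_prediction_is_minus_one(rng):
    t = (rng.uniform(size=(1, 8, 8, 2)) > 0.5).astype(np.float32)
    loss, grad = dice_loss_and_grad(t, t)
    assert loss == pytest.approx(-1.0, abs=1e-5)


def test_masked_loss_gradient_zero_outside_mask(rng):
    pred = rng.uniform(0.1, 0.9, size=(1, 6, 6, 2)).astype(np.float32)
    target = (rng.uniform(size=(1, 6, 6, 2)) > 0.5).astype(np.float32)
    mask = (rng.uniform(size=(1, 6, 6, 2)) > 0.5).astype(np.float32)
    _, grad = dice_loss_and_grad(pred, target, mask=mask)
    assert np.all(grad[mask == 0] == 0.0)
    assert np.any(grad[mask == 1] != 0.0)


def test_plateau_scheduler_halves_exactly_once():
    opt = AdamW(lr=1e-3)
    sched = ReduceLROnPlateau(opt, factor=0.5, patience=5)
    sched.step(1.0)  # initial best
    reductions = [sched.step(1.0) for _ in range(5)]  # constant loss
    assert sum(reductions) == 1
    assert opt.lr == pytest.approx(5e-4)


def test_targets_from_labels_channels():
    lab = np.zeros((12, 12), dtype=np.int32)
    lab[2:6, 2:6] = 1
    lab[6:10, 2:6] = 2  # touching neighbour
    t = targets_from_labels(lab, ("foreground", "boundary", "boundary_distance"))
    assert t.shape == (3, 12, 12)
    assert np.array_equal(t[0] > 0.5, lab > 0)
    assert t[1][5:7, 3].all()  # inter-label interface is boundary
    assert 0.0 <= t[2].min() and t[2].max() == pytest.approx(1.0)


def _tiny_task(rng, n=4, shape=(48, 48)):
    """Blob segmentation task solvable by a tiny net in a few hundred steps."""
    from synrec import PhantomSpec, generate_phantom

    data = []
    for s in range(n):
        vol, lab = generate_phantom(
            PhantomSpec(shape=shape, n_vesicles=2, vesicle_radius_range=(14, 18), seed=s)
        )
        data.append((vol, lab["vesicles"]))
    return data


def test_smoke_training_reduces_validation_loss(rng):
    data = _tiny_task(rng, n=5)
    cfg = UNetConfig(dimensionality=2, levels=2, initial_features=8)
    net = build_unet(cfg, seed=0)
    tc = TrainConfig(
        learning_rate=3e-4, iterations=120, patch_shape=(32, 32), batch_size=2,
        seed=0, epoch_iterations=30,
    )
    trained = train_supervised(net, data, tc)
    assert trained.log[-1]["val_loss"] < trained.log[0]["val_loss"]
    assert all(np.isfinite(e["train_loss"]) for e in trained.log)


def test_training_errors():
    cfg = UNetConfig(dimensionality=2, levels=2, initial_features=4)
    with pytest.raises(ValueError, match="empty"):
        train_supervised(build_unet(cfg), [], TrainConfig(iterations=1, patch_shape=(16, 16)))
    with pytest.raises(ValueError):
        TrainConfig(iterations=0)


def test_tiled_prediction_matches_untiled(rng):
    cfg = UNetConfig(dimensionality=2, levels=2, initial_features=4)
    net = build_unet(cfg, seed=1)
    vol = rng.normal(size=(64, 64)).astype(np.float32)
    full = predict_tiled(net, vol)  # single tile
    tiled = predict_tiled(net, vol, tile_shape=(32, 32), halo=(8, 8))
    assert full.shape == (2, 64, 64)
    assert np.all(full >= 0) and np.all(full <= 1)
    assert np.abs(full - tiled).max() < 1e-4


def test_tiled_prediction_odd_shape(rng):
    net = build_unet(UNetConfig(dimensionality=2, levels=2, initial_features=4), seed=1)
    vol = rng.normal(size=(50, 70)).astype(np.float32)
    out = predict_tiled(net, vol)
    assert out.shape == (2, 50, 70)
    with pytest.raises(ValueError, match="divisible"):
        predict_tiled(net, vol, tile_shape=(31, 31))


def test_checkpoint_roundtrip(tmp_path, rng):
    cfg = UNetConfig(dimensionality=2, levels=2, initial_features=4)
    net = build_unet(cfg, seed=3)
    trained = TrainedModel(net, voxel_size=np.array([1.554, 1.554]))
    path = tmp_path / "model.npz"
    save_checkpoint(trained, path)
    back = load_checkpoint(path)
    assert back.cfg == cfg
    assert np.allclose(back.voxel_size, [1.554, 1.554])
    x = rng.normal(size=(1, 16, 16, 1)).astype(np.float32)
    assert np.array_equal(net.forward(x), back.model.forward(x))


def test_training_statistically_reproducible(rng):
    """Same seed, same data -> identical training trajectory."""
    data = _tiny_task(rng, n=3)
    results = []
    for _ in range(2):
        net = build_unet(UNetConfig(dimensionality=2, levels=2, initial_features=4), seed=0)
        tc = TrainConfig(learning_rate=3e-4, iterations=40, patch_shape=(32, 32),
                         batch_size=2, seed=7, epoch_iterations=20)
        trained = train_supervised(net, data, tc)
        results.append([e["val_loss"] for e in trained.log])
    assert results[0] == results[1]
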