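"""U-Net contracts, soft Dice loss algebra, segmentation evaluation."""

import numpy as np
import pytest

from deshkit import labels as L
from deshkit.io import LabelMap
from deshkit.phantom import PhantomSpec, PhenotypeFlags, render_phantom
from deshkit.preprocess import percentile_normalize
from deshkit.unet import (
    UNetConfig,
    build_unet,
    evaluate_segmentation,
    load_segmenter,
    save_segmenter,
    segment_volume,
    soft_dice_loss,
    train_segmenter,
)

DESH = PhenotypeFlags(desh=True, vd=True, thc=True, sfd=True)
SMALL = dict(grid_shape=(32, 32, 32), voxel_size_mm=(5.0, 5.0, 5.0))


@pytest.fixture(scope="module")
def small_desh_subject():
    return render_phantom(PhantomSpec(phenotype=DESH, seed=3, **SMALL))


@pytest.fixture(scope="module")
def overfit_run(small_desh_subject):
    cfg = UNetConfig(grid_shape=(32, 32, 32), max_iterations=200, augment=False, seed=0)
    model, log = train_segmenter([small_desh_subject], cfg)
    return model, log, small_desh_subject


def test_grid_divisibility_validation():
    UNetConfig(grid_shape=(48, 48, 48))  # 48 = 16 * 3, divisible by 8
    with pytest.raises(ValueError, match="divisible"):
        UNetConfig(grid_shape=(50, 50, 50))
    with pytest.raises(ValueError, match="depth"):
        UNetConfig(depth=1)


def test_output_shape_contract_and_seeded_init():
    cfg = UNetConfig(grid_shape=(16, 16, 16), base_channels=2, seed=5)
    net = build_unet(cfg)
    x = np.random.default_rng(0).random((1, 16, 16, 16), dtype=np.float32)
    logits = net.forward(x)
    assert logits.shape == (cfg.out_categories, 16, 16, 16)

    net2 = build_unet(cfg)
    for p1, p2 in zip(net.params(), net2.params()):
        np.testing.assert_array_equal(p1.value, p2.value)
    net3 = build_unet(UNetConfig(grid_shape=(16, 16, 16), base_channels=2, seed=6))
    assert any(
        not np.array_equal(p1.value, p3.value)
        for p1, p3 in zip(net.params(), net3.params())
    )


def test_forward_rejects_indivisible_grid():
    net = build_unet(UNetConfig(grid_shape=(16, 16, 16), base_channels=2))
    with pytest.raises(ValueError, match="divisible"):
        net.forward(np.zeros((1, 18, 18, 18), np.float32))


# ---------------------------------------------------------------------------
# soft Dice loss


def test_soft_dice_loss_perfect_prediction_is_zero():
    truth = np.random.default_rng(0).integers(0, 3, (6, 6, 6))
    pred = np.zeros((3, 6, 6, 6), np.float32)
    for c in range(3):
        pred[c] = truth == c
    assert soft_dice_loss(pred, truth) == pytest.approx(0.0, abs=1e-9)


def test_soft_dice_loss_uniform_two_categories():
    # uniform prediction over 2 categories, truth all category 1:
    # D_1 = (N + eps) / (1.5 N + eps) ~ 2/3
    n = 4**3
    truth = np.ones((4, 4, 4), int)
    pred = np.full((2, 4, 4, 4), 0.5, np.float32)
    eps = 1e-4
    expect = 1.0 - (n + eps) / (1.5 * n + eps)
    assert soft_dice_loss(pred, truth, epsilon=eps) == pytest.approx(expect, rel=1e-9)


def test_soft_dice_loss_empty_category_not_penalised():
    # truth and prediction both empty for category 2 -> D = eps/eps = 1
    truth = np.zeros((4, 4, 4), int)
    truth[:2] = 1
    pred = np.zeros((3, 4, 4, 4), np.float32)
    pred[0] = truth == 0
    pred[1] = truth == 1
    assert soft_dice_loss(pred, truth) == pytest.approx(0.0, abs=1e-9)


def test_soft_dice_loss_rejects_unnormalised_probabilities():
    truth = np.zeros((4, 4, 4), int)
    pred = np.full((2, 4, 4, 4), 0.7, np.float32)
    with pytest.raises(ValueError, match="sum to 1"):
        soft_dice_loss(pred, truth)


def test_soft_dice_loss_minimal_at_truth(rng):
    """The one-hot truth scores no worse than random probability fields."""
    truth = rng.integers(0, 3, (5, 5, 5))
    onehot = np.stack([(truth == c).astype(np.float32) for c in range(3)])
    best = soft_dice_loss(onehot, truth)
    for _ in range(10):
        p = rng.random((3, 5, 5, 5))
        p /= p.sum(axis=0, keepdims=True)
        assert soft_dice_loss(p.astype(np.float32), truth) >= best - 1e-12


# ---------------------------------------------------------------------------
# evaluation


def _lm(data):
    return LabelMap(np.asarray(data, np.uint8), (1.0, 1.0, 1.0), categories=L.CATEGORIES)


def test_evaluate_segmentation_hand_values():
    truth = np.zeros((10, 10, 10), np.uint8)
    truth[:1] = L.VENTRICLES  # 100 voxels
    pred = np.zeros((10, 10, 10), np.uint8)
    pred[0, :5] = L.VENTRICLES  # 50 voxels, subset
    ev = evaluate_segmentation(_lm(pred), _lm(truth))
    row = ev.loc[L.VENTRICLES]
    assert row.dice == pytest.approx((100 + 1e-4) / (150 + 1e-4))
    assert row.precision == 1.0
    assert row.recall == 0.5
    assert row.volume_difference_ml == pytest.approx(-0.05)

    same = evaluate_segmentation(_lm(truth), _lm(truth))
    assert same.loc[L.VENTRICLES, "dice"] == 1.0
    assert same.loc[L.VENTRICLES, "volume_difference_ml"] == 0.0

    disjoint = np.zeros((10, 10, 10), np.uint8)
    disjoint[5] = L.VENTRICLES  # 100 voxels elsewhere
    ev2 = evaluate_segmentation(_lm(disjoint), _lm(truth))
    assert ev2.loc[L.VENTRICLES, "dice"] == pytest.approx(1e-4 / (200 + 1e-4))


def test_evaluate_segmentation_symmetries():
    rng = np.random.default_rng(3)
    a = _lm(rng.integers(0, 3, (8, 8, 8)))
    b = _lm(rng.integers(0, 3, (8, 8, 8)))
    ab = evaluate_segmentation(a, b)
    ba = evaluate_segmentation(b, a)
    np.testing.assert_allclose(ab.dice, ba.dice)  # Dice symmetric
    np.testing.assert_allclose(ab.precision, ba.recall)  # swap under exchange
    np.testing.assert_allclose(ab.recall, ba.precision)


def test_evaluate_segmentation_spacing_mismatch():
    a = LabelMap(np.zeros((4, 4, 4), np.uint8), (1.0, 1.0, 1.0))
    b = LabelMap(np.zeros((4, 4, 4), np.uint8), (2.0, 1.0, 1.0))
    with pytest.raises(ValueError, match="spacing"):
        evaluate_segmentation(a, b)


# ---------------------------------------------------------------------------
# training behaviour (desk-scale 32^3 runs)


def test_overfit_single_phantom_reaches_high_dice(overfit_run):
    model, log, sub = overfit_run
    pred = segment_volume(model, sub.volume)
    ev = evaluate_segmentation(pred, sub.labelmap)
    assert ev.loc[L.VENTRICLES, "dice"] >= 0.95


def test_training_loss_decreases_over_smoothed_windows(overfit_run):
    _, log, _ = overfit_run
    df = log.to_frame()
    loss = df[df.split == "train"].loss.to_numpy()
    windows = [loss[i : i + 50].mean() for i in range(0, 200, 50)]
    assert windows[-1] < windows[0]
    assert all(b <= a + 0.02 for a, b in zip(windows, windows[1:]))


def test_training_requires_subjects():
    with pytest.raises(ValueError, match="empty"):
        train_segmenter([], UNetConfig())


def test_seed_changes_final_parameters(small_desh_subject):
    cfg = dict(grid_shape=(32, 32, 32), max_iterations=3, augment=False)
    m1, _ = train_segmenter([small_desh_subject], UNetConfig(seed=0, **cfg))
    m2, _ = train_segmenter([small_desh_subject], UNetConfig(seed=1, **cfg))
    assert any(
        not np.array_equal(p1.value, p2.value)
        for p1, p2 in zip(m1.params(), m2.params())
    )


def test_segmentation_is_deterministic_and_checkpoint_roundtrips(overfit_run, tmp_path):
    model, _, sub = overfit_run
    a = segment_volume(model, sub.volume)
    b = segment_volume(model, sub.volume)
    np.testing.assert_array_equal(a.data, b.data)
    assert set(np.unique(a.data)) <= set(L.CATEGORIES)

    save_segmenter(model, tmp_path / "ckpt.npz")
    back = load_segmenter(tmp_path / "ckpt.npz")
    c = segment_volume(back, sub.volume)
    np.testing.assert_array_equal(a.data, c.data)
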