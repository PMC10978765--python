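"""Stage 1: volumetric semantic segmentation with a 4-level 3D U-Net.

The encoder applies, per level, two (conv 3x3x3 + batch norm + ReLU)
blocks followed by 2x2x2 max pooling; the symmetric decoder upsamples with
stride-2 up-convolutions (kernel 3) and concatenates the corresponding
encoder feature map before two further conv blocks; a final 1x1x1
convolution emits per-voxel category scores.  Training minimises a
smoothed soft Dice loss

    D_c = (2 sum(p_c t_c) + eps) / (sum(p_c) + sum(t_c) + eps),
    loss = 1 - mean over foreground categories of D_c,

with eps = 1e-4, on percentile-normalised intensities with on-the-fly
rigid+scale augmentation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from deshkit import labels as L
from deshkit.io import LabelMap, Volume
from deshkit.preprocess import AugmentParams, augment_pair, percentile_normalize
from deshkit.nn import Adam, ConvBlock, Conv3d, MaxPool3d, UpConv3d
from deshkit.stats import DICE_EPSILON

__all__ = [
    "UNetConfig",
    "TrainingLog",
    "Segmenter",
    "build_unet",
    "soft_dice_loss",
    "train_segmenter",
    "segment_volume",
    "evaluate_segmentation",
]


@dataclass
class UNetConfig:
    depth: int = 4
    base_channels: int = 8
    out_categories: int = len(L.CATEGORIES)
    grid_shape: tuple[int, int, int] = (64, 64, 64)
    epsilon: float = DICE_EPSILON
    learning_rate: float = 3e-3
    max_iterations: int = 300
    augment: bool = True
    val_interval: int = 25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth < 2:
            raise ValueError("depth must be >= 2")
        if self.out_categories < 2:
            raise ValueError("out_categories must be >= 2")
        div = 2 ** (self.depth - 1)
        if any(s % div for s in self.grid_shape):
            raise ValueError(
                f"grid {tuple(self.grid_shape)} not divisible by 2^(depth-1)={div}"
            )


@dataclass
class TrainingLog:
    """Per-iteration metrics for training and internal validation."""

    records: list[dict] = field(default_factory=list)

    def append(self, **kwargs) -> None:
        self.records.append(kwargs)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.records)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


class Segmenter:
    """The 3D U-Net with explicit forward/backward over the U topology."""

    def __init__(self, config: UNetConfig):
        self.config = config
        rng = np.random.default_rng(np.random.SeedSequence(entropy=config.seed & 0x7FFFFFFF))
        d = config.depth
        ch = [config.base_channels * 2**l for l in range(d)]
        self.ch = ch
        self.enc = []
        c_prev = 1
        for l in range(d):
            self.enc.append(
                (ConvBlock(c_prev, ch[l], rng=rng), ConvBlock(ch[l], ch[l], rng=rng))
            )
            c_prev = ch[l]
        self.pools = [MaxPool3d() for _ in range(d - 1)]
        self.ups = [UpConv3d(ch[l + 1], ch[l], rng=rng) for l in range(d - 1)]
        self.dec = [
            (ConvBlock(2 * ch[l], ch[l], rng=rng), ConvBlock(ch[l], ch[l], rng=rng))
            for l in range(d - 1)
        ]
        self.head = Conv3d(ch[0], config.out_categories, k=1, rng=rng)
        self._layers = (
            [b for pair in self.enc for b in pair]
            + self.pools
            + self.ups
            + [b for pair in self.dec for b in pair]
            + [self.head]
        )

    def params(self):
        return [p for layer in self._layers for p in layer.params()]

    def set_train(self, mode: bool) -> None:
        for layer in self._layers:
            layer.set_train(mode)

    def forward(self, x: np.ndarray) -> np.ndarray:
        """(1, D, H, W) normalised intensities -> (C, D, H, W) logits."""
        cfg = self.config
        div = 2 ** (cfg.depth - 1)
        if any(s % div for s in x.shape[1:]):
            raise ValueError(f"input grid {x.shape[1:]} not divisible by {div}")
        d = cfg.depth
        skips = []
        h = x.astype(np.float32)
        for l in range(d - 1):
            h = self.enc[l][1].forward(self.enc[l][0].forward(h))
            skips.append(h)
            h = self.pools[l].forward(h)
        h = self.enc[d - 1][1].forward(self.enc[d - 1][0].forward(h))
        for l in range(d - 2, -1, -1):
            u = self.ups[l].forward(h)
            h = np.concatenate([skips[l], u], axis=0)
            h = self.dec[l][1].forward(self.dec[l][0].forward(h))
        return self.head.forward(h)

    def backward(self, dlogits: np.ndarray) -> None:
        d = self.config.depth
        dh = self.head.backward(dlogits)
        dskips = [None] * (d - 1)
        for l in range(d - 1):
            dh = self.dec[l][0].backward(self.dec[l][1].backward(dh))
            c = self.ch[l]
            dskips[l] = dh[:c]
            dh = self.ups[l].backward(dh[c:])
        dh = self.enc[d - 1][0].backward(self.enc[d - 1][1].backward(dh))
        for l in range(d - 2, -1, -1):
            dh = self.pools[l].backward(dh)
            dh = dh + dskips[l]
            dh = self.enc[l][0].backward(self.enc[l][1].backward(dh))


def build_unet(config: UNetConfig) -> Segmenter:
    """Build a seeded U-Net; identical seeds give identical parameters."""
    return Segmenter(config)


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=0, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=0, keepdims=True)


def _one_hot(truth: np.ndarray, n_cat: int) -> np.ndarray:
    oh = np.zeros((n_cat,) + truth.shape, dtype=np.float32)
    for c in range(n_cat):
        oh[c] = truth == c
    return oh


def soft_dice_loss(
    pred: np.ndarray,
    truth: LabelMap | np.ndarray,
    epsilon: float = DICE_EPSILON,
    foreground: Sequence[int] | None = None,
) -> float:
    """Smoothed soft Dice loss of per-voxel category probabilities.

    ``pred`` has shape (C, ...) and must sum to 1 over categories within
    1e-5 per voxel; ``truth`` is an integer category grid.  The loss is
    1 minus the mean smoothed Dice over foreground categories (all
    categories except code 0 unless ``foreground`` is given).
    """
    loss, _ = _dice_loss_and_grad(pred, truth, epsilon, foreground, check=True)
    return loss


def _dice_loss_and_grad(pred, truth, epsilon, foreground=None, check=False):
    t = truth.data if isinstance(truth, LabelMap) else np.asarray(truth)
    if pred.shape[1:] != t.shape:
        raise ValueError(f"pred grid {pred.shape[1:]} vs truth grid {t.shape}")
    n_cat = pred.shape[0]
    if check:
        sums = pred.sum(axis=0)
        if not np.allclose(sums, 1.0, atol=1e-5):
            raise ValueError("probability rows do not sum to 1 within 1e-5")
    if foreground is None:
        foreground = list(range(1, n_cat))
    oh = _one_hot(t, n_cat)
    dgrad = np.zeros_like(pred, dtype=np.float64)
    dices = []
    for c in foreground:
        p_c = pred[c].astype(np.float64)
        t_c = oh[c].astype(np.float64)
        inter = float((p_c * t_c).sum())
        denom = float(p_c.sum() + t_c.sum()) + epsilon
        d_c = (2.0 * inter + epsilon) / denom
        dices.append(d_c)
        # d(D_c)/d(p_c) = (2 t_c * denom - (2 inter + eps)) / denom^2
        dgrad[c] = (2.0 * t_c * denom - (2.0 * inter + epsilon)) / denom**2
    loss = 1.0 - float(np.mean(dices))
    dgrad *= -1.0 / len(foreground)
    return loss, dgrad


def _loss_from_logits(logits, truth, epsilon, foreground=None):
    p = _softmax(logits)
    loss, dp = _dice_loss_and_grad(p, truth, epsilon, foreground)
    # softmax jacobian: dL/dz = p * (dL/dp - sum_c p_c dL/dp_c)
    dot = (dp * p).sum(axis=0, keepdims=True)
    dlogits = (p * (dp - dot)).astype(np.float32)
    return loss, p, dlogits


def _quick_metrics(pred_codes, truth_codes, categories):
    """Mean foreground Dice / precision / recall of an argmax prediction."""
    dices, precs, recs = [], [], []
    for c in categories:
        if c == 0:
            continue
        p = pred_codes == c
        t = truth_codes == c
        tp = float(np.count_nonzero(p & t))
        np_, nt = float(np.count_nonzero(p)), float(np.count_nonzero(t))
        dices.append((2 * tp + DICE_EPSILON) / (np_ + nt + DICE_EPSILON))
        precs.append(tp / np_ if np_ else (1.0 if nt == 0 else 0.0))
        recs.append(tp / nt if nt else (1.0 if np_ == 0 else 0.0))
    return float(np.mean(dices)), float(np.mean(precs)), float(np.mean(recs))


def train_segmenter(
    train_subjects,
    config: UNetConfig,
    val_subjects=None,
    augment_params: AugmentParams | None = None,
) -> tuple[Segmenter, TrainingLog]:
    """Train the U-Net on phantom subjects with on-the-fly augmentation.

    Each iteration draws one training subject at random, normalises its
    intensities by percentile, optionally augments the (volume, labels)
    pair, and takes one Adam step on the soft Dice loss.  Per-iteration
    loss/Dice/precision/recall are logged; validation metrics every
    ``config.val_interval`` iterations.
    """
    if not train_subjects:
        raise ValueError("empty training split")
    model = build_unet(config)
    opt = Adam(model.params(), lr=config.learning_rate)
    rng = np.random.default_rng(np.random.SeedSequence(entropy=(config.seed + 1) & 0x7FFFFFFF))
    aug = augment_params or AugmentParams()
    log = TrainingLog()

    norm = [percentile_normalize(s.volume) for s in train_subjects]
    for it in range(config.max_iterations):
        i = int(rng.integers(len(train_subjects)))
        v, m = norm[i], train_subjects[i].labelmap
        if config.augment:
            v, m = augment_pair(v, m, aug, rng=rng)
        x = v.data[None].astype(np.float32)
        model.set_train(True)
        logits = model.forward(x)
        # the training objective averages over ALL categories (background
        # included) so that every channel receives direct gradient; the
        # foreground-only Dice remains the reported evaluation quantity
        loss, p, dlogits = _loss_from_logits(
            logits, m.data, config.epsilon, foreground=list(range(config.out_categories))
        )
        opt.zero_grad()
        model.backward(dlogits)
        opt.step()

        pred_codes = p.argmax(axis=0)
        dice, prec, rec = _quick_metrics(pred_codes, m.data, range(config.out_categories))
        rec_row = {"iteration": it, "split": "train", "loss": loss,
                   "dice": dice, "precision": prec, "recall": rec}
        log.append(**rec_row)

        if val_subjects and (it + 1) % config.val_interval == 0:
            vloss, vdice, vprec, vrec = _validate(model, val_subjects, config)
            log.append(iteration=it, split="internal_validation", loss=vloss,
                       dice=vdice, precision=vprec, recall=vrec)
    return model, log


def _validate(model: Segmenter, subjects, config: UNetConfig):
    model.set_train(False)
    losses, dices, precs, recs = [], [], [], []
    for s in subjects:
        x = percentile_normalize(s.volume).data[None]
        logits = model.forward(x)
        loss, p, _ = _loss_from_logits(
            logits, s.labelmap.data, config.epsilon,
            foreground=list(range(config.out_categories)),
        )
        pred = p.argmax(axis=0)
        d, pr, rc = _quick_metrics(pred, s.labelmap.data, range(config.out_categories))
        losses.append(loss); dices.append(d); precs.append(pr); recs.append(rc)
    model.set_train(True)
    return tuple(float(np.mean(v)) for v in (losses, dices, precs, recs))


def segment_volume(model: Segmenter, v: Volume, normalized: bool = False) -> LabelMap:
    """Segment one volume: per-voxel argmax category (ties -> lowest code).

    Intensities are percentile-normalised exactly as in training unless
    ``normalized=True`` asserts the caller already did.
    """
    if not normalized:
        v = percentile_normalize(v)
    model.set_train(False)
    logits = model.forward(v.data[None].astype(np.float32))
    # np.argmax returns the first (lowest-code) maximum on ties
    codes = logits.argmax(axis=0).astype(np.uint8)
    return LabelMap(codes, v.voxel_size_mm, v.origin_mm,
                    categories=tuple(range(model.config.out_categories)))


def save_segmenter(model: Segmenter, path) -> None:
    """Single-file checkpoint: config and parameters (normalisation
    statistics are instance statistics, recomputed per input)."""
    import json

    arrays = {f"param_{i}": p.value for i, p in enumerate(model.params())}
    np.savez(path, config=json.dumps(asdict(model.config)), **arrays)


def load_segmenter(path) -> Segmenter:
    import json

    with np.load(path, allow_pickle=False) as data:
        cfg_d = json.loads(str(data["config"]))
        cfg_d["grid_shape"] = tuple(cfg_d["grid_shape"])
        model = Segmenter(UNetConfig(**cfg_d))
        for i, p in enumerate(model.params()):
            p.value[...] = data[f"param_{i}"]
    return model


def evaluate_segmentation(pred: LabelMap, truth: LabelMap, epsilon: float = DICE_EPSILON) -> pd.DataFrame:
    """Per-category hard Dice, precision, recall and volume difference (mL)."""
    if pred.shape != truth.shape:
        raise ValueError(f"grids differ: {pred.shape} vs {truth.shape}")
    if not np.allclose(pred.voxel_size_mm, truth.voxel_size_mm):
        raise ValueError(
            f"voxel spacing differs: {pred.voxel_size_mm} vs {truth.voxel_size_mm}"
        )
    vox_ml = pred.voxel_volume_mm3 / 1000.0
    cats = sorted(set(pred.categories) | set(truth.categories))
    rows = []
    for c in cats:
        p = pred.data == c
        t = truth.data == c
        tp = float(np.count_nonzero(p & t))
        np_, nt = float(np.count_nonzero(p)), float(np.count_nonzero(t))
        rows.append({
            "category": c,
            "name": L.CATEGORY_NAMES.get(c, str(c)),
            "dice": (2 * tp + epsilon) / (np_ + nt + epsilon),
            "precision": tp / np_ if np_ else (1.0 if nt == 0 else 0.0),
            "recall": tp / nt if nt else (1.0 if np_ == 0 else 0.0),
            "volume_difference_ml": (np_ - nt) * vox_ml,
        })
    return pd.DataFrame(rows).set_index("category")
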