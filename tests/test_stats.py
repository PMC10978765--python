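"""Index arithmetic, smoothed Dice, ROC/Youden and Pearson CI checks
against independent brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from deshkit.partition import CompartmentVolumes
from deshkit.stats import (
    DICE_EPSILON,
    compute_indices,
    dice_score,
    pearson_with_ci,
    roc_analysis,
)

# ---------------------------------------------------------------------------
# independent oracles


def dice_oracle(x, y, eps=DICE_EPSILON):
    """Explicit voxel-set Dice via triple loops."""
    inter = nx = ny = 0
    for i in range(x.shape[0]):
        for j in range(x.shape[1]):
            for k in range(x.shape[2]):
                if x[i, j, k]:
                    nx += 1
                if y[i, j, k]:
                    ny += 1
                if x[i, j, k] and y[i, j, k]:
                    inter += 1
    return (2 * inter + eps) / (nx + ny + eps)


def auc_oracle(scores, labels):
    """Concordant-pair count (+1/2 for ties) over all pos/neg pairs."""
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def youden_oracle(scores, labels):
    """Exhaustive scan over every cut point (midpoints + sentinels)."""
    uniq = sorted(set(scores))
    span = max(uniq[-1] - uniq[0], 1.0)
    cands = [uniq[0] - span] + [(a + b) / 2 for a, b in zip(uniq, uniq[1:])] + [uniq[-1] + span]
    best = (-1.0, None)
    for c in cands:
        sens = sum(1 for s, l in zip(scores, labels) if l and s >= c) / sum(labels)
        spec = sum(1 for s, l in zip(scores, labels) if not l and s < c) / (
            len(labels) - sum(labels)
        )
        if sens + spec > best[0] + 1e-12:
            best = (sens + spec, c)
    return best


# ---------------------------------------------------------------------------
# indices


def test_indices_from_published_group_means():
    # Hakim-group automated T1 volume means: 129.2 / 90.2 / 17.9 mL
    hakim = compute_indices(
        CompartmentVolumes(129.2, 90.2, 17.9, 222.9)
    )
    assert hakim.desh_index == pytest.approx(12.26, abs=0.005)
    assert hakim.venthi_index == pytest.approx(7.218, abs=0.005)
    assert hakim.sylhi_index == pytest.approx(5.039, abs=0.005)
    # healthy-group means: 26.9 / 42.9 / 42.5 mL
    normal = compute_indices(CompartmentVolumes(26.9, 42.9, 42.5, 195.2))
    assert normal.desh_index == pytest.approx(1.642, abs=0.005)
    assert normal.venthi_index == pytest.approx(0.633, abs=0.005)
    assert normal.sylhi_index == pytest.approx(1.009, abs=0.005)


@settings(max_examples=200, deadline=None)
@given(
    vent=st.floats(0.1, 500), syl=st.floats(0.1, 500),
    hc=st.floats(0.1, 200), k=st.floats(0.01, 100),
)
def test_index_identity_and_scale_invariance(vent, syl, hc, k):
    """desh = venthi + sylhi exactly; indices invariant under volume rescale."""
    idx = compute_indices(CompartmentVolumes(vent, syl, hc, 100.0))
    assert idx.desh_index == idx.venthi_index + idx.sylhi_index
    scaled = compute_indices(CompartmentVolumes(vent * k, syl * k, hc * k, 100.0 * k))
    assert scaled.desh_index == pytest.approx(idx.desh_index, rel=1e-9)
    assert scaled.venthi_index == pytest.approx(idx.venthi_index, rel=1e-9)


def test_index_monotone_in_ventricular_volume():
    base = compute_indices(CompartmentVolumes(50.0, 40.0, 30.0, 100.0))
    bigger = compute_indices(CompartmentVolumes(80.0, 40.0, 30.0, 100.0))
    assert bigger.venthi_index > base.venthi_index
    assert bigger.desh_index > base.desh_index
    assert bigger.sylhi_index == base.sylhi_index


def test_indices_guard_against_empty_high_convexity():
    with pytest.raises(ValueError, match="high-convexity"):
        compute_indices(CompartmentVolumes(10.0, 10.0, 0.0, 10.0))


# ---------------------------------------------------------------------------
# Dice


def test_dice_hand_values():
    x = np.zeros((5, 5, 5), bool)
    assert dice_score(x, x) == 1.0  # empty vs empty -> eps/eps
    x[:2] = True  # 50 voxels
    y = np.zeros((5, 5, 5), bool)
    y[:4] = True  # 100 voxels, x subset of y
    assert dice_score(x, y) == pytest.approx((100 + 1e-4) / (150 + 1e-4))
    z = np.zeros((5, 5, 5), bool)
    z[4] = True  # disjoint
    assert dice_score(y[:, :, :], z) == pytest.approx(1e-4 / (125 + 1e-4))


def test_dice_matches_bruteforce_oracle_and_is_symmetric(rng):
    for _ in range(25):
        shape = tuple(rng.integers(2, 9, size=3))
        x = rng.random(shape) < 0.4
        y = rng.random(shape) < 0.4
        assert dice_score(x, y) == pytest.approx(dice_oracle(x, y), rel=1e-12)
        assert dice_score(x, y) == dice_score(y, x)


def test_dice_shape_mismatch():
    with pytest.raises(ValueError, match="shape"):
        dice_score(np.zeros((2, 2, 2)), np.zeros((3, 2, 2)))


# ---------------------------------------------------------------------------
# ROC


def test_roc_perfect_separation():
    res = roc_analysis([0.1, 0.2, 0.8, 0.9], [False, False, True, True], n_boot=50, seed=0)
    assert res.auc == 1.0
    assert res.sensitivity == 1.0 and res.specificity == 1.0
    assert 0.2 < res.threshold < 0.8


def test_roc_all_ties_gives_half():
    res = roc_analysis([1.0] * 6, [True, False, True, False, True, False], n_boot=20, seed=0)
    assert res.auc == 0.5


def test_roc_enumerated_example():
    scores = [1, 3, 2, 4, 5, 0]
    labels = [False, False, True, True, True, False]
    res = roc_analysis(scores, labels, n_boot=50, seed=0)
    assert res.auc == pytest.approx(8 / 9)
    assert res.sensitivity + res.specificity == pytest.approx(5 / 3)
    assert res.threshold_tied  # two cuts tie; the smaller one is kept
    assert res.threshold == pytest.approx(1.5)


def test_roc_matches_pair_counting_and_exhaustive_youden(rng):
    for _ in range(30):
        n = int(rng.integers(4, 31))
        labels = np.zeros(n, bool)
        labels[: max(1, n // 3)] = True
        rng.shuffle(labels)
        if labels.all() or not labels.any():
            continue
        scores = np.round(rng.normal(size=n) + labels * rng.uniform(0, 2), 2)
        res = roc_analysis(scores, labels, n_boot=10, seed=1)
        assert res.auc == pytest.approx(auc_oracle(scores, labels), rel=1e-12)
        best_j, _ = youden_oracle(list(scores), list(labels))
        assert res.sensitivity + res.specificity == pytest.approx(best_j)


def test_roc_requires_both_classes():
    with pytest.raises(ValueError, match="both classes"):
        roc_analysis([1.0, 2.0], [True, True], n_boot=10, seed=0)


def test_roc_bootstrap_ci_is_seeded_and_ordered():
    rng = np.random.default_rng(5)
    scores = np.concatenate([rng.normal(2, 1, 15), rng.normal(0, 1, 25)])
    labels = np.array([True] * 15 + [False] * 25)
    a = roc_analysis(scores, labels, n_boot=200, seed=9)
    b = roc_analysis(scores, labels, n_boot=200, seed=9)
    assert a.auc_ci == b.auc_ci
    assert a.auc_ci[0] <= a.auc <= a.auc_ci[1]


# ---------------------------------------------------------------------------
# Pearson


def test_pearson_exact_lines():
    x = np.arange(10.0)
    r, _ = pearson_with_ci(x, 2 * x + 1)
    assert r == pytest.approx(1.0)
    r, _ = pearson_with_ci(x, -x)
    assert r == pytest.approx(-1.0)


def test_pearson_matches_hand_formula():
    x = np.array([1.0, 2, 3, 4])
    y = np.array([1.0, 2, 3, 5])
    r, ci = pearson_with_ci(x, y)
    cov = np.mean((x - x.mean()) * (y - y.mean()))
    expect = cov / (x.std() * y.std())
    assert r == pytest.approx(expect, rel=1e-12)
    assert ci[0] < r < ci[1]


def test_pearson_zero_variance_rejected():
    with pytest.raises(ValueError, match="variance"):
        pearson_with_ci([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
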