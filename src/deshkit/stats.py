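"""Volumetric DESH indices and the evaluation statistics built on them.

The three ratio indices quantify the disproportion of CSF distribution that
defines DESH: with ``V`` the total ventricular volume, ``S`` the Sylvian
fissure + basal cistern volume and ``H`` the high-convexity subarachnoid
space volume (all in mL),

    DESH index   = (V + S) / H
    Venthi index =  V / H
    Sylhi index  =  S / H

so that ``desh = venthi + sylhi`` holds as an algebraic identity.  High
indices mean crowded high-convexity sulci relative to enlarged ventricles
and Sylvian fissures, i.e. a DESH-like pattern.

Detection of DESH from an index is calibrated by ROC analysis: AUC from the
empirical ROC curve (ties counted one half), the operating threshold chosen
to maximise sensitivity + specificity (Youden), and 95% confidence
intervals by a seeded nonparametric bootstrap over subjects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "IndexSet",
    "RocResult",
    "compute_indices",
    "dice_score",
    "roc_analysis",
    "pearson_with_ci",
]

#: Smoothing constant of the Dice coefficient (keeps empty-vs-empty at 1).
DICE_EPSILON = 1e-4


@dataclass(frozen=True)
class IndexSet:
    """The three dimensionless DESH ratio indices."""

    desh_index: float
    venthi_index: float
    sylhi_index: float

    def as_dict(self) -> dict[str, float]:
        return {
            "desh_index": self.desh_index,
            "venthi_index": self.venthi_index,
            "sylhi_index": self.sylhi_index,
        }


def compute_indices(volumes) -> IndexSet:
    """Compute DESH/Venthi/Sylhi indices from compartment volumes (mL).

    ``volumes`` is anything exposing ``total_ventricles_ml``,
    ``sylvian_basal_ml`` and ``high_convexity_sas_ml`` attributes (a
    :class:`deshkit.partition.CompartmentVolumes`) or a mapping with those
    keys.  Raises ``ValueError`` when the high-convexity volume is not
    strictly positive (the indices are undefined there).
    """
    if hasattr(volumes, "total_ventricles_ml"):
        vent = float(volumes.total_ventricles_ml)
        syl = float(volumes.sylvian_basal_ml)
        hc = float(volumes.high_convexity_sas_ml)
    else:
        vent = float(volumes["total_ventricles_ml"])
        syl = float(volumes["sylvian_basal_ml"])
        hc = float(volumes["high_convexity_sas_ml"])
    if hc <= 0:
        raise ValueError(f"high-convexity SAS volume must be > 0 mL, got {hc}")
    venthi = vent / hc
    sylhi = syl / hc
    return IndexSet(desh_index=venthi + sylhi, venthi_index=venthi, sylhi_index=sylhi)


def dice_score(x: np.ndarray, y: np.ndarray, epsilon: float = DICE_EPSILON) -> float:
    """Smoothed Dice overlap (2|X∩Y| + ε) / (|X| + |Y| + ε) of two binary masks."""
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape:
        raise ValueError(f"mask shapes differ: {x.shape} vs {y.shape}")
    x = x.astype(bool)
    y = y.astype(bool)
    inter = float(np.count_nonzero(x & y))
    total = float(np.count_nonzero(x) + np.count_nonzero(y))
    return (2.0 * inter + epsilon) / (total + epsilon)


@dataclass(frozen=True)
class RocResult:
    """ROC summary for one index: AUC, Youden threshold, and bootstrap CIs."""

    auc: float
    auc_ci: tuple[float, float]
    threshold: float
    sensitivity: float
    sensitivity_ci: tuple[float, float]
    specificity: float
    specificity_ci: tuple[float, float]
    threshold_ci: tuple[float, float]
    n_positive: int
    n_negative: int
    threshold_tied: bool = False

    def as_dict(self) -> dict:
        return {
            "auc": self.auc,
            "auc_ci": list(self.auc_ci),
            "threshold": self.threshold,
            "threshold_ci": list(self.threshold_ci),
            "sensitivity": self.sensitivity,
            "sensitivity_ci": list(self.sensitivity_ci),
            "specificity": self.specificity,
            "specificity_ci": list(self.specificity_ci),
            "n_positive": self.n_positive,
            "n_negative": self.n_negative,
        }


def _auc_rank(scores: np.ndarray, labels: np.ndarray) -> float:
    # Mann-Whitney form of the trapezoidal empirical-ROC area: ranks of the
    # positive scores among all scores, ties counted one half.
    ranks = sps.rankdata(scores)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    u = ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def _youden_threshold(scores: np.ndarray, labels: np.ndarray) -> tuple[float, float, float, bool]:
    """Exhaustive scan over candidate cuts; positive call is score >= cut.

    Candidates are midpoints between consecutive sorted unique scores plus
    sentinels below/above the data.  Ties in sensitivity + specificity break
    toward the smaller threshold (favouring sensitivity).
    """
    uniq = np.unique(scores)
    span = max(uniq[-1] - uniq[0], 1.0)
    cands = np.concatenate(
        [[uniq[0] - 0.5 * span], (uniq[:-1] + uniq[1:]) / 2.0, [uniq[-1] + 0.5 * span]]
    )
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    best = (-np.inf, np.nan, np.nan, np.nan)
    tied = False
    for c in cands:
        call = scores >= c
        sens = float((call & labels).sum()) / n_pos
        spec = float((~call & ~labels).sum()) / n_neg
        j = sens + spec
        if j > best[0] + 1e-12:
            best = (j, float(c), sens, spec)
            tied = False
        elif abs(j - best[0]) <= 1e-12:
            tied = True  # keep the earlier (smaller) threshold
    return best[1], best[2], best[3], tied


def roc_analysis(
    scores,
    labels,
    n_boot: int = 2000,
    seed: int | np.random.Generator = 0,
) -> RocResult:
    """ROC/AUC with Youden-optimal threshold and bootstrap percentile CIs.

    ``labels`` are booleans with True = DESH-positive; higher scores are
    treated as more DESH-like.  Raises ``ValueError`` when only one class
    is present.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be matching 1D arrays")
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present for ROC analysis")

    auc = _auc_rank(scores, labels)
    thr, sens, spec, tied = _youden_threshold(scores, labels)

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    boot = np.empty((n_boot, 4))
    n = scores.size
    for b in range(n_boot):
        while True:
            idx = rng.integers(0, n, size=n)
            lb = labels[idx]
            if lb.any() and not lb.all():
                break
        sc = scores[idx]
        t, se, sp, _ = _youden_threshold(sc, lb)
        boot[b] = (_auc_rank(sc, lb), t, se, sp)

    lo, hi = np.percentile(boot, [2.5, 97.5], axis=0)
    return RocResult(
        auc=auc,
        auc_ci=(float(lo[0]), float(hi[0])),
        threshold=thr,
        threshold_ci=(float(lo[1]), float(hi[1])),
        sensitivity=sens,
        sensitivity_ci=(float(lo[2]), float(hi[2])),
        specificity=spec,
        specificity_ci=(float(lo[3]), float(hi[3])),
        n_positive=n_pos,
        n_negative=n_neg,
        threshold_tied=tied,
    )


def pearson_with_ci(x, y, confidence: float = 0.95) -> tuple[float, tuple[float, float]]:
    """Pearson product-moment r with a Fisher-z confidence interval."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need matching samples with n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance input")
    res = sps.pearsonr(x, y)
    ci = res.confidence_interval(confidence_level=confidence)
    return float(res.statistic), (float(ci.low), float(ci.high))
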