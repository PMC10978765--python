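"""Stage 2: multimodal CNN classification of DESH, VD, THC and SFD.

Each of the four binary determinations is made by its own small 3D CNN
over a task-specific mask derived from the six-category segmentation:

* DESH - the whole intracranial CSF mask (ventricles + all SAS),
* VD   - the total-ventricle mask,
* THC  - the high-convexity SAS mask,
* SFD  - the Sylvian fissure + basal cistern mask,

min-max normalised to [0, 1], with the subject's age and sex passed
through an embedding layer and concatenated to the globally pooled
convolutional features before the fully connected head; a two-way softmax
emits the probability score per task.  Convolution blocks are
conv(3,3,3) + batch norm + ReLU + channel self-attention
(squeeze-and-excitation) + max pooling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from deshkit import labels as L
from deshkit.io import LabelMap, Volume
from deshkit.nn import Adam, ConvBlock, Linear, MaxPool3d
from deshkit.preprocess import AugmentParams, augment_pair, minmax_normalize
from deshkit.unet import TrainingLog

__all__ = [
    "ClassifierConfig",
    "ClassificationResult",
    "TASKS",
    "TASK_MASKS",
    "assemble_classifier_input",
    "build_classifier",
    "train_classifier",
    "classify_subject",
    "evaluate_classification",
]

TASKS = ("desh", "vd", "thc", "sfd")

#: Task -> label codes whose union forms the input mask.
TASK_MASKS: dict[str, tuple[int, ...]] = {
    "desh": L.CSF_CATEGORIES,
    "vd": (L.VENTRICLES,),
    "thc": (L.HIGH_CONVEXITY_SAS,),
    "sfd": (L.SYLVIAN_BASAL,),
}


@dataclass
class ClassifierConfig:
    conv_channels: tuple[int, ...] = (8, 16, 32)
    covariate_embedding_dim: int = 8
    tasks: tuple[str, ...] = TASKS
    input_downsample: int = 2
    learning_rate: float = 1e-3
    max_iterations: int = 120
    batch_size: int = 4
    augment: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.conv_channels:
            raise ValueError("need at least one conv block")
        if not self.tasks:
            raise ValueError("tasks must be nonempty")
        unknown = set(self.tasks) - set(TASKS)
        if unknown:
            raise ValueError(f"unknown tasks {sorted(unknown)}")


@dataclass
class ClassificationResult:
    """Per-task positive-class softmax probability and binary label."""

    probabilities: dict[str, float]
    labels: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.labels:
            self.labels = {t: p >= 0.5 for t, p in self.probabilities.items()}


def assemble_classifier_input(subject, task: str) -> tuple[Volume, dict]:
    """Build the task-specific mask volume and covariates for one subject.

    ``subject`` needs a six-category ``labelmap``, ``age_years`` and
    ``sex``.  The mask is min-max normalised to [0, 1]; covariates are the
    raw age (standardised later with training-split statistics) and a sex
    one-hot.
    """
    if task not in TASK_MASKS:
        raise ValueError(f"unknown task {task!r}; expected one of {TASKS}")
    lmap: LabelMap = subject.labelmap
    mask = lmap.mask(*TASK_MASKS[task]).astype(np.float32)
    vol = minmax_normalize(Volume(mask, lmap.voxel_size_mm, lmap.origin_mm))
    age = getattr(subject, "age_years", None)
    sex = getattr(subject, "sex", None)
    if age is None or (isinstance(age, float) and np.isnan(age)):
        raise ValueError(f"subject {getattr(subject, 'subject_id', '?')} missing age covariate")
    if sex not in ("male", "female"):
        raise ValueError(f"subject {getattr(subject, 'subject_id', '?')} missing sex covariate")
    cov = {"age_years": float(age), "sex_male": float(sex == "male"), "sex_female": float(sex == "female")}
    return vol, cov


def _downsample(data: np.ndarray, f: int) -> np.ndarray:
    if f <= 1:
        return data.astype(np.float32)
    d, h, w = (s - s % f for s in data.shape)
    x = data[:d, :h, :w].reshape(d // f, f, h // f, f, w // f, f)
    return x.mean(axis=(1, 3, 5)).astype(np.float32)


class _TaskNet:
    """One binary task: conv/attention blocks -> GAP (+ covariates) -> FC."""

    def __init__(self, config: ClassifierConfig, rng: np.random.Generator):
        self.blocks = []
        c_prev = 1
        for c in config.conv_channels:
            self.blocks.append((ConvBlock(c_prev, c, rng=rng, attention=True), MaxPool3d()))
            c_prev = c
        self.embed = Linear(3, config.covariate_embedding_dim, rng=rng)
        self.fc = Linear(c_prev + config.covariate_embedding_dim, 2, rng=rng)
        self._layers = [b for pair in self.blocks for b in pair] + [self.embed, self.fc]

    def params(self):
        return [p for l in self._layers for p in l.params()]

    def set_train(self, mode: bool) -> None:
        for l in self._layers:
            l.set_train(mode)

    def forward(self, x: np.ndarray, cov: np.ndarray) -> np.ndarray:
        h = x
        for block, pool in self.blocks:
            h = pool.forward(block.forward(h))
        self._feat_shape = h.shape
        feat = h.mean(axis=(1, 2, 3))
        e = self.embed.forward(cov)
        self._emask = e > 0
        e = e * self._emask
        self._z = np.concatenate([feat, e])
        return self.fc.forward(self._z)

    def backward(self, dlogits: np.ndarray) -> np.ndarray:
        dz = self.fc.backward(dlogits)
        c = self._feat_shape[0]
        dfeat, de = dz[:c], dz[c:]
        dcov = self.embed.backward(de * self._emask)
        n = float(np.prod(self._feat_shape[1:]))
        dh = np.broadcast_to(
            (dfeat / n)[:, None, None, None], self._feat_shape
        ).astype(np.float32).copy()
        for block, pool in reversed(self.blocks):
            dh = block.backward(pool.backward(dh))
        return dcov


class Classifier:
    """Four independent task networks plus training-split covariate scaling."""

    def __init__(self, config: ClassifierConfig):
        self.config = config
        rng = np.random.default_rng(np.random.SeedSequence(entropy=config.seed & 0x7FFFFFFF))
        self.nets = {t: _TaskNet(config, rng) for t in config.tasks}
        self.age_mean = 0.0
        self.age_sd = 1.0

    def _cov_vector(self, cov: dict) -> np.ndarray:
        age = (cov["age_years"] - self.age_mean) / self.age_sd
        return np.array([age, cov["sex_male"], cov["sex_female"]], dtype=np.float32)

    def task_probability(self, task: str, x: np.ndarray, cov: dict) -> float:
        logits = self.nets[task].forward(x, self._cov_vector(cov))
        z = logits - logits.max()
        e = np.exp(z)
        return float(e[1] / e.sum())


def build_classifier(config: ClassifierConfig) -> Classifier:
    """Seeded construction; identical seeds give identical parameters."""
    return Classifier(config)


def _prepare_input(subject, task: str, config: ClassifierConfig,
                   augment: bool = False, rng=None, aug: AugmentParams | None = None):
    vol, cov = assemble_classifier_input(subject, task)
    if augment:
        vol, _ = augment_pair(vol, subject.labelmap, aug or AugmentParams(), rng=rng)
    x = _downsample(vol.data, config.input_downsample)[None]
    return x, cov


def train_classifier(
    train_subjects,
    config: ClassifierConfig,
    truth_flags: dict[str, list[bool]] | None = None,
    augment_params: AugmentParams | None = None,
) -> tuple[Classifier, TrainingLog]:
    """Train the four task networks by cross-entropy with augmentation.

    Ground-truth flags default to the phantoms' construction phenotypes;
    ``truth_flags`` overrides them (e.g. for label-shuffle controls).
    Raises ``ValueError`` when a task sees only one class in training.
    """
    if not train_subjects:
        raise ValueError("empty training split")
    model = build_classifier(config)
    ages = [s.age_years for s in train_subjects]
    model.age_mean = float(np.mean(ages))
    model.age_sd = float(np.std(ages)) or 1.0

    flags = truth_flags or {
        t: [bool(getattr(s.phenotype, t)) for s in train_subjects] for t in config.tasks
    }
    for t in config.tasks:
        if len(set(flags[t])) < 2:
            raise ValueError(
                f"task {t!r} has a single class in the training split; resample the cohort"
            )

    rng = np.random.default_rng(np.random.SeedSequence(entropy=(config.seed + 1) & 0x7FFFFFFF))
    aug = augment_params or AugmentParams()
    log = TrainingLog()
    n = len(train_subjects)
    for task in config.tasks:
        net = model.nets[task]
        opt = Adam(net.params(), lr=config.learning_rate)
        y = np.asarray(flags[task], dtype=int)
        for it in range(config.max_iterations):
            idx = rng.integers(0, n, size=config.batch_size)
            opt.zero_grad()
            losses, correct = [], 0
            for i in idx:
                x, cov = _prepare_input(
                    train_subjects[i], task, config,
                    augment=config.augment, rng=rng, aug=aug,
                )
                net.set_train(True)
                logits = net.forward(x, model._cov_vector(cov))
                z = logits - logits.max()
                p = np.exp(z) / np.exp(z).sum()
                losses.append(-float(np.log(max(p[y[i]], 1e-12))))
                correct += int((p[1] >= 0.5) == bool(y[i]))
                dlogits = (p - np.eye(2)[y[i]]).astype(np.float32) / config.batch_size
                net.backward(dlogits)
            opt.step()
            log.append(iteration=it, task=task, split="train",
                       loss=float(np.mean(losses)), accuracy=correct / config.batch_size)
    return model, log


def classify_subject(model: Classifier, subject) -> ClassificationResult:
    """Deterministic per-task probabilities and labels for one subject."""
    probs = {}
    for task in model.config.tasks:
        x, cov = _prepare_input(subject, task, model.config)
        model.nets[task].set_train(False)
        probs[task] = model.task_probability(task, x, cov)
    return ClassificationResult(probabilities=probs)


def evaluate_classification(results: list[ClassificationResult], truth: list) -> dict:
    """Per-task accuracy, mean predicted-class softmax score, discrepancies.

    ``truth`` is a list of objects with phenotype flags (PhantomSubject or
    PhenotypeFlags).  The mean probability score averages, over all
    subjects, the softmax probability the model assigned to its own
    predicted category (the primary summary); the mean over positive calls
    only is also reported.
    """
    if len(results) != len(truth):
        raise ValueError(f"length mismatch: {len(results)} results vs {len(truth)} truths")
    tasks = list(results[0].probabilities)
    out: dict = {}
    for task in tasks:
        agree, scores, pos_scores, discrepancies = 0, [], [], []
        for i, (res, tr) in enumerate(zip(results, truth)):
            flags = tr.phenotype if hasattr(tr, "phenotype") else tr
            t_lab = bool(getattr(flags, task))
            p_pos = res.probabilities[task]
            m_lab = res.labels[task]
            scores.append(p_pos if m_lab else 1.0 - p_pos)
            if m_lab:
                pos_scores.append(p_pos)
            if m_lab == t_lab:
                agree += 1
            else:
                sid = getattr(tr, "subject_id", str(i))
                discrepancies.append({"subject": sid, "task": task,
                                      "truth": t_lab, "predicted": m_lab,
                                      "probability": p_pos})
        out[task] = {
            "accuracy": agree / len(results),
            "mean_probability_score": float(np.mean(scores)),
            "mean_probability_score_positive_calls": float(np.mean(pos_scores)) if pos_scores else float("nan"),
            "discrepancies": discrepancies,
        }
    return out
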