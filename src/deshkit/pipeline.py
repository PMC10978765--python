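"""End-to-end orchestration: cohort -> split -> segment -> partition ->
indices -> classify -> calibrate -> evaluate -> report.

Two evaluation pathways are provided: the full pipeline through the
trained U-Net, and an oracle pathway that uses the phantoms' ground-truth
label maps, which isolates the correctness of the index/ROC machinery from
segmentation quality (mirroring the manual-vs-automated comparison that
validation studies of this kind report).  Index thresholds are calibrated
on the internal-validation split only and frozen before the external
split is evaluated.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from deshkit import labels as L
from deshkit.classifier import (
    ClassifierConfig,
    classify_subject,
    evaluate_classification,
    train_classifier,
)
from deshkit.io import RunConfig, substream, write_provenance
from deshkit.partition import compartment_volumes, partition_sas
from deshkit.phantom import sample_cohort
from deshkit.stats import RocResult, compute_indices, roc_analysis
from deshkit.unet import (
    UNetConfig,
    evaluate_segmentation,
    segment_volume,
    train_segmenter,
)

__all__ = [
    "SplitPlan",
    "ReportBundle",
    "make_split",
    "subject_indices",
    "calibrate_thresholds",
    "run_end_to_end",
]

INDEX_NAMES = ("desh_index", "venthi_index", "sylhi_index")


@dataclass(frozen=True)
class SplitPlan:
    """Stratified training / internal-validation / external-validation split."""

    training_ids: tuple[str, ...]
    internal_validation_ids: tuple[str, ...]
    external_validation_ids: tuple[str, ...]
    desh_counts: dict = field(default_factory=dict)

    def splits(self) -> dict[str, tuple[str, ...]]:
        return {
            "training": self.training_ids,
            "internal_validation": self.internal_validation_ids,
            "external_validation": self.external_validation_ids,
        }


def _allocate(n: int, fractions) -> list[int]:
    """Largest-remainder allocation of n items over the fractions."""
    raw = [n * f for f in fractions]
    base = [int(np.floor(r)) for r in raw]
    rem = n - sum(base)
    order = np.argsort([b - r for b, r in zip(base, raw)])  # largest remainder first
    for j in range(rem):
        base[order[j]] += 1
    return base


def make_split(subjects, fractions=(0.70, 0.19, 0.11), seed: int = 0,
               require_both_classes: bool = True) -> SplitPlan:
    """Stratified-by-DESH split into training/internal/external sets.

    Fractions must sum to 1; within each phenotype class subjects are
    shuffled (seeded) and allocated by largest remainder, which keeps the
    DESH fraction of every split within one subject of the cohort fraction.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {fractions}")
    rng = substream(seed, "split")
    by_class: dict[bool, list] = {True: [], False: []}
    for s in subjects:
        by_class[bool(s.phenotype.desh)].append(s.subject_id)
    parts: dict[int, list[str]] = {0: [], 1: [], 2: []}
    desh_counts: dict[str, dict] = {}
    for cls in (True, False):
        ids = sorted(by_class[cls])
        rng.shuffle(ids)
        counts = _allocate(len(ids), fractions)
        pos = 0
        for k, c in enumerate(counts):
            parts[k].extend(ids[pos : pos + c])
            pos += c
    names = ("training", "internal_validation", "external_validation")
    desh_set = set(by_class[True])
    for k, name in enumerate(names):
        n_desh = sum(1 for i in parts[k] if i in desh_set)
        desh_counts[name] = {"desh": n_desh, "non_desh": len(parts[k]) - n_desh}
        if not parts[k]:
            raise ValueError(f"split '{name}' is empty at n={len(subjects)}")
        if require_both_classes and (n_desh == 0 or n_desh == len(parts[k])):
            raise ValueError(
                f"split '{name}' is single-class (DESH {n_desh}/{len(parts[k])}); "
                "enlarge the cohort or adjust fractions"
            )
    return SplitPlan(
        training_ids=tuple(parts[0]),
        internal_validation_ids=tuple(parts[1]),
        external_validation_ids=tuple(parts[2]),
        desh_counts=desh_counts,
    )


def subject_indices(subject, pathway: str = "oracle", segmenter=None) -> dict:
    """DESH/Venthi/Sylhi indices for one subject via the chosen pathway.

    ``oracle`` uses the phantom's ground-truth label map; ``unet`` segments
    the intensity volume with the trained model, then applies the landmark
    partition to the predicted SAS.
    """
    if pathway == "oracle":
        vols = compartment_volumes(subject.labelmap)
    elif pathway == "unet":
        if segmenter is None:
            raise ValueError("unet pathway requires a trained segmenter")
        pred = segment_volume(segmenter, subject.volume)
        sas = pred.mask(*L.SAS_CATEGORIES)
        part = partition_sas(
            sas, _seeds_in_mask(subject.sylvian_seeds_mm, sas, pred), subject.landmarks,
            pred.voxel_size_mm, pred.origin_mm,
        )
        merged = part.data.copy()
        merged[pred.data == L.VENTRICLES] = L.VENTRICLES
        vols = compartment_volumes(
            type(part)(merged, part.voxel_size_mm, part.origin_mm, L.CATEGORIES)
        )
    else:
        raise ValueError(f"unknown pathway {pathway!r}")
    idx = compute_indices(vols)
    return {"volumes": vols, **idx.as_dict()}


def _seeds_in_mask(seeds_mm, mask, labelmap):
    """Keep only the annotated Sylvian seeds that fall inside the predicted SAS."""
    kept = []
    for s in seeds_mm:
        idx = tuple(
            int(round((s[i] - labelmap.origin_mm[i]) / labelmap.voxel_size_mm[i]))
            for i in range(3)
        )
        if all(0 <= idx[i] < mask.shape[i] for i in range(3)) and mask[idx]:
            kept.append(s)
    return kept


def calibrate_thresholds(index_rows: pd.DataFrame, n_boot: int = 500, seed: int = 0) -> dict[str, RocResult]:
    """Youden-optimal thresholds per index from internal-split indices+flags.

    ``index_rows`` needs columns desh (bool) and the three index columns.
    """
    out = {}
    for j, name in enumerate(INDEX_NAMES):
        out[name] = roc_analysis(
            index_rows[name].to_numpy(), index_rows["desh"].to_numpy(),
            n_boot=n_boot, seed=substream(seed, f"bootstrap-{name}"),
        )
    return out


@dataclass
class ReportBundle:
    """Tables mirroring a segmentation/classification/ROC validation report."""

    segmentation_table: pd.DataFrame
    classification_table: pd.DataFrame
    roc_table: pd.DataFrame
    indices: pd.DataFrame
    thresholds: dict
    external_performance: pd.DataFrame
    provenance: dict

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.segmentation_table.to_csv(out / "segmentation_table.csv")
        self.classification_table.to_csv(out / "classification_table.csv", index=False)
        self.roc_table.to_csv(out / "roc_table.csv", index=False)
        self.indices.to_csv(out / "indices.csv", index=False)
        self.external_performance.to_csv(out / "external_performance.csv", index=False)
        (out / "provenance.json").write_text(json.dumps(self.provenance, indent=2, default=str))


def run_end_to_end(config: RunConfig) -> ReportBundle:
    """Execute the full chain on a synthetic cohort; reproducible per seed.

    Stages: generate cohort, split (stratified), optionally train the
    segmenter and classifier (``pathway: unet``) or use ground-truth labels
    (``pathway: oracle``), compute volumes and indices, calibrate index
    thresholds on the internal split, and evaluate on the frozen external
    split.  Any stage failure raises with the stage name and subject id.
    """
    seed = int(config["seed"])
    pathway = config["pathway"]
    stage = "generate"
    try:
        subjects, manifest = sample_cohort(
            int(config["cohort_size"]), float(config["desh_fraction"]),
            config["contrast"], seed=seed,
            grid_shape=tuple(config["grid_shape"]),
            voxel_size_mm=tuple(config["voxel_size_mm"]),
            noise_sd=float(config["noise_sd"]),
        )
        by_id = {s.subject_id: s for s in subjects}

        stage = "split"
        plan = make_split(subjects, tuple(config["split_fractions"]), seed=seed)

        segmenter = None
        seg_table = pd.DataFrame()
        clf_table = pd.DataFrame()
        if pathway == "unet":
            stage = "train-seg"
            seg_cfg = UNetConfig(
                grid_shape=tuple(config["grid_shape"]),
                base_channels=int(config["seg_base_channels"]),
                max_iterations=int(config["seg_iterations"]),
                augment=bool(config["augment"]), seed=seed,
            )
            train_subs = [by_id[i] for i in plan.training_ids]
            val_subs = [by_id[i] for i in plan.internal_validation_ids]
            segmenter, _ = train_segmenter(train_subs, seg_cfg, val_subjects=None)

            stage = "evaluate-seg"
            rows = []
            for sid in plan.internal_validation_ids + plan.external_validation_ids:
                s = by_id[sid]
                pred = segment_volume(segmenter, s.volume)
                ev = evaluate_segmentation(pred, s.labelmap)
                ev["subject_id"] = sid
                rows.append(ev.reset_index())
            seg_long = pd.concat(rows, ignore_index=True)
            seg_table = seg_long.groupby("name")[
                ["dice", "precision", "recall", "volume_difference_ml"]
            ].agg(["mean", "std"])

            stage = "train-clf"
            clf_cfg = ClassifierConfig(
                max_iterations=int(config["clf_iterations"]),
                batch_size=int(config["clf_batch_size"]),
                augment=bool(config["augment"]), seed=seed,
            )
            clf, _ = train_classifier(train_subs, clf_cfg)

            stage = "classify"
            ext = [by_id[i] for i in plan.internal_validation_ids + plan.external_validation_ids]
            results = [classify_subject(clf, s) for s in ext]
            ev = evaluate_classification(results, ext)
            clf_table = pd.DataFrame(
                [{"task": t, "accuracy": ev[t]["accuracy"],
                  "mean_probability_score": ev[t]["mean_probability_score"],
                  "n_discrepancies": len(ev[t]["discrepancies"])} for t in ev]
            )

        stage = "indices"
        rows = []
        for s in subjects:
            r = subject_indices(s, pathway=pathway, segmenter=segmenter)
            rows.append({
                "subject_id": s.subject_id, "desh": s.phenotype.desh,
                "split": _which_split(s.subject_id, plan),
                **{k: r[k] for k in INDEX_NAMES},
                **r["volumes"].as_dict(),
            })
        indices = pd.DataFrame(rows)

        stage = "calibrate"
        internal = indices[indices.split == "internal_validation"]
        thresholds = calibrate_thresholds(internal, n_boot=int(config["n_boot"]), seed=seed)
        roc_table = pd.DataFrame([
            {"index": name, "contrast": config["contrast"], **res.as_dict()}
            for name, res in thresholds.items()
        ])

        stage = "evaluate"
        external = indices[indices.split == "external_validation"]
        perf_rows = []
        for name, res in thresholds.items():
            call = external[name].to_numpy() >= res.threshold
            truth = external["desh"].to_numpy()
            sens = float((call & truth).sum() / truth.sum())
            spec = float(((~call) & (~truth)).sum() / (~truth).sum())
            perf_rows.append({"index": name, "threshold": res.threshold,
                              "sensitivity": sens, "specificity": spec,
                              "youden": sens + spec - 1.0})
        external_perf = pd.DataFrame(perf_rows)
    except Exception as err:
        raise RuntimeError(f"pipeline failed at stage '{stage}': {err}") from err

    bundle = ReportBundle(
        segmentation_table=seg_table,
        classification_table=clf_table,
        roc_table=roc_table,
        indices=indices,
        thresholds={k: v.as_dict() for k, v in thresholds.items()},
        external_performance=external_perf,
        provenance={"seed": seed, "pathway": pathway, "config_hash": config.hash(),
                    "splits": plan.splits(), "desh_counts": plan.desh_counts},
    )
    out_dir = config["output_dir"]
    if out_dir:
        bundle.write(out_dir)
        write_provenance(config, Path(out_dir) / "run_provenance.json")
    return bundle


def _which_split(sid: str, plan: SplitPlan) -> str:
    for name, ids in plan.splits().items():
        if sid in ids:
            return name
    return "unassigned"
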