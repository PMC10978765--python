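"""Synthetic cranial phantoms with known CSF-compartment geometry.

Each phantom is a schematic head: a cranial ellipsoid filled with
parenchyma, into which six label categories are carved — paired
ellipsoidal lateral ventricles plus midline third/fourth ventricles, two
oblique slab-shaped Sylvian fissures and a basal-cistern shell, a thin
high-convexity SAS sheet at the vertex (within 30 mm of the midsagittal
plane, bounded by the same landmark rule the partition module applies),
and a residual outer SAS shell.  Compartment sizes are fitted by bisection
so that realised voxel volumes match the requested targets within 5%.

Compartment volume targets are drawn from a built-in calibration table of
per-group (DESH vs non-DESH) means and SDs for each contrast, reflecting
published cohort statistics for Hakim-disease patients and healthy
controls.  A single per-subject severity latent couples the compartments
(ventricles and Sylvian/basal volumes rise with severity while the
high-convexity SAS shrinks in the DESH group), which keeps the two
phenotype groups separated in index space the way real DESH cohorts are.

Geometry is deliberately schematic, not anatomically realistic: the
downstream mathematics consumes masks and volumes only.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import json

import numpy as np
import pandas as pd

from deshkit import labels as L
from deshkit.io import LabelMap, Volume, substream, write_labelmap, write_volume
from deshkit.partition import CompartmentVolumes, Landmarks, compartment_volumes, high_convexity_rule

__all__ = [
    "CompartmentTargets",
    "PhenotypeFlags",
    "PhantomSpec",
    "PhantomSubject",
    "CALIBRATION_ML",
    "phenotype_to_targets",
    "render_phantom",
    "sample_cohort",
]

Contrast = Literal["T1_like", "T2_like"]

#: Calibration table: (mean, SD) of automated compartment volumes in mL per
#: contrast and phenotype group.  The other-SAS row is derived as
#: total SAS minus the two named SAS compartments (its SD taken from the
#: total-SAS row).
CALIBRATION_ML: dict[str, dict[str, dict[str, tuple[float, float]]]] = {
    "T1_like": {
        "desh": {
            "total_ventricles_ml": (129.2, 35.1),
            "sylvian_basal_ml": (90.2, 12.0),
            "high_convexity_sas_ml": (17.9, 3.7),
            "other_sas_ml": (222.9, 35.7),
        },
        "normal": {
            "total_ventricles_ml": (26.9, 19.4),
            "sylvian_basal_ml": (42.9, 10.3),
            "high_convexity_sas_ml": (42.5, 12.1),
            "other_sas_ml": (195.2, 60.6),
        },
    },
    "T2_like": {
        "desh": {
            "total_ventricles_ml": (150.3, 45.2),
            "sylvian_basal_ml": (88.6, 9.0),
            "high_convexity_sas_ml": (7.3, 4.2),
            "other_sas_ml": (192.5, 53.2),
        },
        "normal": {
            "total_ventricles_ml": (25.5, 9.9),
            "sylvian_basal_ml": (37.7, 8.9),
            "high_convexity_sas_ml": (32.2, 12.8),
            "other_sas_ml": (149.0, 57.7),
        },
    },
}

#: Intensity assignment per contrast (arbitrary scanner units).
_INTENSITY = {
    "T1_like": {"background": 20.0, "parenchyma": 600.0, "csf": 150.0},
    "T2_like": {"background": 20.0, "parenchyma": 350.0, "csf": 900.0},
}

#: Latent-severity truncation and jitter weight of the target sampler.
_LATENT_TRUNC = 2.4
_JITTER_TRUNC = 2.0
_SHARED_WEIGHT = 0.95


@dataclass(frozen=True)
class PhenotypeFlags:
    """Binary imaging phenotype: DESH and its three component signs."""

    desh: bool = False
    vd: bool = False
    thc: bool = False
    sfd: bool = False

    def __post_init__(self) -> None:
        if self.desh and not (self.thc and self.sfd):
            raise ValueError("inconsistent flags: DESH requires both THC and SFD")

    def as_dict(self) -> dict[str, bool]:
        return {"desh": self.desh, "vd": self.vd, "thc": self.thc, "sfd": self.sfd}


@dataclass(frozen=True)
class CompartmentTargets:
    """Requested compartment volumes (mL); all strictly positive."""

    total_ventricles_ml: float
    sylvian_basal_ml: float
    high_convexity_sas_ml: float
    other_sas_ml: float

    def __post_init__(self) -> None:
        for name in ("total_ventricles_ml", "sylvian_basal_ml", "high_convexity_sas_ml", "other_sas_ml"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")

    @property
    def total_sas_ml(self) -> float:
        return self.sylvian_basal_ml + self.high_convexity_sas_ml + self.other_sas_ml


@dataclass(frozen=True)
class PhantomSpec:
    """Everything needed to deterministically render one phantom."""

    grid_shape: tuple[int, int, int] = (64, 64, 64)
    voxel_size_mm: tuple[float, float, float] = (2.5, 2.5, 2.5)
    phenotype: PhenotypeFlags = PhenotypeFlags()
    targets: CompartmentTargets | None = None
    contrast: Contrast = "T2_like"
    noise_sd: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s < 32 for s in self.grid_shape):
            raise ValueError(f"grid_shape must be >= 32 per axis, got {self.grid_shape}")
        if any(v <= 0 for v in self.voxel_size_mm):
            raise ValueError(f"voxel_size_mm must be positive, got {self.voxel_size_mm}")
        if self.contrast not in ("T1_like", "T2_like"):
            raise ValueError(f"unknown contrast {self.contrast!r}")


@dataclass
class PhantomSubject:
    """One rendered phantom with its ground truth."""

    subject_id: str
    volume: Volume
    labelmap: LabelMap
    landmarks: Landmarks
    sylvian_seeds_mm: list[tuple[float, float, float]]
    age_years: float
    sex: str  # "male" | "female"
    phenotype: PhenotypeFlags
    true_volumes: CompartmentVolumes
    targets: CompartmentTargets | None = None
    contrast: str = "T2_like"


def _floor_ml(voxel_size_mm) -> float:
    # Resolvability floor: a target must span enough voxels for the 5%
    # fidelity contract to be meaningful on the given grid.
    vox_ml = float(np.prod(voxel_size_mm)) / 1000.0
    return max(0.5, 128.0 * vox_ml)


def _trunc_normal(rng: np.random.Generator, bound: float) -> float:
    while True:
        z = rng.standard_normal()
        if abs(z) <= bound:
            return float(z)


def phenotype_to_targets(
    phenotype: PhenotypeFlags,
    age_years: float,
    seed: int,
    contrast: Contrast = "T2_like",
    voxel_size_mm=(2.5, 2.5, 2.5),
) -> CompartmentTargets:
    """Sample compartment volume targets for one subject.

    DESH phantoms draw from the DESH-group calibration column, non-DESH
    phantoms from the normal column.  A shared severity latent (truncated
    normal, ±2.4 SD, weight 0.95) couples the four compartments — with its
    sign flipped for the high-convexity SAS in the DESH group, where greater
    severity means tighter convexity sulci — plus a small independent jitter
    per compartment.  Values are floored at a grid-resolvability minimum.
    Deterministic per (phenotype, seed, contrast).
    """
    group = "desh" if phenotype.desh else "normal"
    table = CALIBRATION_ML[contrast][group]
    rng = np.random.default_rng(np.random.SeedSequence(entropy=int(seed) & 0x7FFFFFFF))
    u = _trunc_normal(rng, _LATENT_TRUNC)
    floor = _floor_ml(voxel_size_mm)
    values = {}
    for name, (mu, sd) in table.items():
        sign = -1.0 if (group == "desh" and name == "high_convexity_sas_ml") else 1.0
        e = _trunc_normal(rng, _JITTER_TRUNC)
        z = _SHARED_WEIGHT * sign * u + (1.0 - _SHARED_WEIGHT) * e
        values[name] = max(floor, mu + sd * z)
    return CompartmentTargets(**values)


# ---------------------------------------------------------------------------
# Geometry


class _Geometry:
    """Precomputed world-coordinate fields for one grid."""

    def __init__(self, shape, voxel_size_mm):
        self.shape = tuple(shape)
        self.voxel_size_mm = tuple(voxel_size_mm)
        self.vox_ml = float(np.prod(voxel_size_mm)) / 1000.0
        # world centre of the grid
        self.centre = tuple((shape[i] - 1) / 2.0 * voxel_size_mm[i] for i in range(3))
        axes = [voxel_size_mm[i] * np.arange(shape[i]) - self.centre[i] for i in range(3)]
        self.x, self.y, self.z = np.meshgrid(*axes, indexing="ij", sparse=True)
        # cranial ellipsoid semi-axes, scaled down if the field of view is small
        fov = [shape[i] * voxel_size_mm[i] for i in range(3)]
        s = min(1.0, min(fov[0] / 150.0, fov[1] / 160.0, fov[2] / 134.0))
        self.semi = (70.0 * s, 75.0 * s, 62.0 * s)
        self.scale = s
        a, b, c = self.semi
        self.rho = np.sqrt((self.x / a) ** 2 + (self.y / b) ** 2 + (self.z / c) ** 2)
        self.skull = self.rho <= 1.0

    def ellipsoid(self, centre, semi) -> np.ndarray:
        cx, cy, cz = centre
        a, b, c = semi
        return ((self.x - cx) / a) ** 2 + ((self.y - cy) / b) ** 2 + ((self.z - cz) / c) ** 2 <= 1.0


def _ventricle_region(g: _Geometry, s: float) -> np.ndarray:
    k = g.scale
    lat_l = g.ellipsoid((-15 * k, 8 * k, 8 * k), (9 * k * s, 32 * k * s, 12 * k * s))
    lat_r = g.ellipsoid((+15 * k, 8 * k, 8 * k), (9 * k * s, 32 * k * s, 12 * k * s))
    third = g.ellipsoid((0, 5 * k, -5 * k), (3 * k * s, 15 * k * s, 10 * k * s))
    fourth = g.ellipsoid((0, -25 * k, -35 * k), (4 * k * s, 10 * k * s, 8 * k * s))
    return (lat_l | lat_r | third | fourth) & g.skull


def _sylvian_region(g: _Geometry, t: float, vent: np.ndarray) -> np.ndarray:
    k = g.scale
    half = 10.0 * k * t
    interior = g.rho <= 0.80
    box = (
        (g.y >= -40 * k) & (g.y <= 40 * k) & (g.z >= -32 * k) & (g.z <= 10 * k)
    )
    slabs = np.zeros(g.shape, dtype=bool)
    for sign in (-1.0, 1.0):
        # oblique: the slab leans inward going down and twists slightly in y
        xc = sign * (38.0 * k + 0.25 * (g.z + 10 * k) + 0.08 * g.y)
        slabs |= np.abs(g.x - xc) <= half
    slabs &= box
    m = (
        (g.x / (26 * k)) ** 2
        + ((g.y + 5 * k) / (26 * k)) ** 2
        + ((g.z + 34 * k) / (14 * k)) ** 2
    )
    basal = (m <= 1.0) & (m >= 1.0 - 0.5 * t)
    return (slabs | basal) & interior & ~vent


def _shell(g: _Geometry, delta: float) -> np.ndarray:
    return (g.rho > 1.0 - delta) & g.skull


def _bisect_fit(region_fn, target_voxels: int, lo: float, hi: float, name: str, tol: float = 0.05):
    """Fit a monotone scalar geometry parameter to a voxel-count target."""
    n_hi = int(region_fn(hi).sum())
    if n_hi < target_voxels * (1 - tol):
        raise ValueError(
            f"compartment '{name}' target of {target_voxels} voxels unachievable "
            f"within the grid (maximum {n_hi})"
        )
    n_lo = int(region_fn(lo).sum())
    if n_lo > target_voxels * (1 + tol):
        raise ValueError(
            f"compartment '{name}' target of {target_voxels} voxels below the "
            f"smallest renderable size ({n_lo})"
        )
    best = (abs(n_hi - target_voxels), hi)
    for _ in range(48):
        mid = 0.5 * (lo + hi)
        n = int(region_fn(mid).sum())
        if abs(n - target_voxels) < best[0]:
            best = (abs(n - target_voxels), mid)
        if n < target_voxels:
            lo = mid
        elif n > target_voxels:
            hi = mid
        else:
            return mid
    return best[1]


def render_phantom(
    spec: PhantomSpec,
    age_years: float = 70.0,
    sex: str = "female",
    subject_id: str = "phantom",
) -> PhantomSubject:
    """Render one phantom: label map, intensity volume, landmarks, truth.

    Raises ``ValueError`` when a target volume cannot be realised within 5%
    on the requested grid (never silently truncates).
    """
    targets = spec.targets
    if targets is None:
        targets = phenotype_to_targets(
            spec.phenotype, age_years, spec.seed, spec.contrast, spec.voxel_size_mm
        )
    g = _Geometry(spec.grid_shape, spec.voxel_size_mm)
    k = g.scale
    to_vox = lambda ml: max(1, int(round(ml / g.vox_ml)))

    # 1. ventricles
    s_v = _bisect_fit(
        lambda s: _ventricle_region(g, s), to_vox(targets.total_ventricles_ml),
        0.05, 2.6, "total_ventricles",
    )
    vent = _ventricle_region(g, s_v)

    # landmarks follow the fitted geometry
    cx, cy, cz = g.centre
    ztop = cz + (8.0 + 12.0 * s_v) * k
    lm = Landmarks(
        ac_mm=(cx, cy + 10 * k, cz - 10 * k),
        pc_mm=(cx, cy - 15 * k, cz - 10 * k),
        midsagittal_point_mm=(cx, cy, cz),
        midsagittal_normal=(1.0, 0.0, 0.0),
        genu_front_mm=(cx, cy + 30 * k, cz - 5 * k),
        ventricle_body_top_z_mm=ztop,
        callosomarginal_posterior_mm=cy - 45 * k,
    )
    rule = high_convexity_rule(
        g.shape, lm, spec.voxel_size_mm, (0.0, 0.0, 0.0), _lateral_bound(g)
    )

    # 2. Sylvian fissures + basal cistern
    t_y = _bisect_fit(
        lambda t: _sylvian_region(g, t, vent), to_vox(targets.sylvian_basal_ml),
        0.005, 1.0, "sylvian_basal",
    )
    sylvian = _sylvian_region(g, t_y, vent)

    # 3. high-convexity SAS sheet (inside the landmark rule region)
    hc_fn = lambda d: _shell(g, d) & rule & ~vent
    d_h = _bisect_fit(hc_fn, to_vox(targets.high_convexity_sas_ml), 0.001, 0.6, "high_convexity_sas")
    hc = hc_fn(d_h)

    # 4. residual outer SAS shell (outside the rule region)
    o_fn = lambda d: _shell(g, d) & ~rule & ~vent & ~sylvian
    d_o = _bisect_fit(o_fn, to_vox(targets.other_sas_ml), 0.001, 0.6, "other_sas")
    other = o_fn(d_o)

    label = np.zeros(g.shape, dtype=np.uint8)
    label[g.skull] = L.PARENCHYMA
    label[other] = L.OTHER_SAS
    label[hc] = L.HIGH_CONVEXITY_SAS
    label[sylvian] = L.SYLVIAN_BASAL
    label[vent] = L.VENTRICLES

    labelmap = LabelMap(label, spec.voxel_size_mm, (0.0, 0.0, 0.0), categories=L.CATEGORIES)
    realized = compartment_volumes(labelmap)
    for name in ("total_ventricles_ml", "sylvian_basal_ml", "high_convexity_sas_ml", "other_sas_ml"):
        want = getattr(targets, name)
        got = getattr(realized, name)
        if abs(got - want) / want > 0.05:
            raise ValueError(
                f"compartment '{name}' realised {got:.2f} mL vs target {want:.2f} mL (>5%)"
            )

    inten = _INTENSITY[spec.contrast]
    vol = np.full(g.shape, inten["background"], dtype=np.float32)
    vol[label == L.PARENCHYMA] = inten["parenchyma"]
    vol[np.isin(label, L.CSF_CATEGORIES)] = inten["csf"]
    if spec.noise_sd > 0:
        rng = substream(spec.seed, "phantom-noise")
        vol = vol + rng.normal(0.0, spec.noise_sd, size=g.shape).astype(np.float32)

    # one seed per 26-connected Sylvian/basal component (exact recovery)
    seeds = _component_seeds(sylvian, spec.voxel_size_mm)

    return PhantomSubject(
        subject_id=subject_id,
        volume=Volume(vol, spec.voxel_size_mm),
        labelmap=labelmap,
        landmarks=lm,
        sylvian_seeds_mm=seeds,
        age_years=float(age_years),
        sex=sex,
        phenotype=spec.phenotype,
        true_volumes=realized,
        targets=targets,
        contrast=spec.contrast,
    )


def _lateral_bound(g: _Geometry) -> float:
    """Lateral high-convexity bound in mm, shrunk with the field of view."""
    from deshkit.partition import LATERAL_BOUND_MM

    return LATERAL_BOUND_MM * g.scale


def _component_seeds(mask: np.ndarray, voxel_size_mm) -> list[tuple[float, float, float]]:
    """One world-mm seed voxel per 26-connected component of the mask."""
    from scipy import ndimage

    if not mask.any():
        return []
    comp, n = ndimage.label(mask, structure=np.ones((3, 3, 3), dtype=bool))
    spacing = np.asarray(voxel_size_mm)
    seeds = []
    for c in range(1, n + 1):
        idx = np.argwhere(comp == c)[0]
        seeds.append(tuple(float(v) for v in idx * spacing))
    return seeds


# ---------------------------------------------------------------------------
# Cohorts


def _sample_demographics(rng: np.random.Generator, desh: bool) -> tuple[float, str]:
    # DESH phantoms mirror the older patient group of real cohorts.
    if desh:
        age = float(np.clip(rng.normal(75.0, 7.0), 60.0, 92.0))
    else:
        age = float(np.clip(rng.normal(54.0, 15.0), 22.0, 88.0))
    sex = "male" if rng.random() < 0.43 else "female"
    return age, sex


def _sample_flags(rng: np.random.Generator, desh: bool) -> PhenotypeFlags:
    if desh:
        return PhenotypeFlags(desh=True, vd=bool(rng.random() < 0.95), thc=True, sfd=True)
    vd = bool(rng.random() < 0.02)
    thc = bool(rng.random() < 0.02)
    sfd = bool(rng.random() < 0.02) and not thc  # never THC and SFD together without DESH
    return PhenotypeFlags(desh=False, vd=vd, thc=thc, sfd=sfd)


def sample_cohort(
    n: int,
    desh_fraction: float,
    contrast: Contrast = "T2_like",
    seed: int = 0,
    grid_shape=(64, 64, 64),
    voxel_size_mm=(2.5, 2.5, 2.5),
    noise_sd: float = 20.0,
    output_dir: str | Path | None = None,
) -> tuple[list[PhantomSubject], pd.DataFrame]:
    """Generate a phantom cohort plus its manifest.

    Approximately ``n * desh_fraction`` subjects are DESH-positive, with
    older ages in the DESH group.  When ``output_dir`` is given, volumes
    and label maps are written as NIfTI with JSON landmark sidecars and the
    manifest as CSV.  Deterministic per seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not (0.0 <= desh_fraction <= 1.0):
        raise ValueError("desh_fraction must be in [0, 1]")
    n_desh = int(round(n * desh_fraction))
    warning = None
    if n_desh == 0 and desh_fraction > 0:
        warning = f"desh_fraction {desh_fraction} rounds to 0 DESH subjects at n={n}"

    master = substream(seed, "phantom-cohort")
    subjects: list[PhantomSubject] = []
    rows = []
    for i in range(n):
        desh = i < n_desh
        sid = f"sub-{i + 1:03d}"
        rng = np.random.default_rng(master.integers(0, 2**31 - 1))
        age, sex = _sample_demographics(rng, desh)
        flags = _sample_flags(rng, desh)
        sub_seed = int(rng.integers(0, 2**31 - 1))
        spec = PhantomSpec(
            grid_shape=tuple(grid_shape),
            voxel_size_mm=tuple(voxel_size_mm),
            phenotype=flags,
            contrast=contrast,
            noise_sd=noise_sd,
            seed=sub_seed,
        )
        subject = render_phantom(spec, age_years=age, sex=sex, subject_id=sid)
        subjects.append(subject)
        row = {
            "subject_id": sid,
            "age_years": round(age, 1),
            "sex": sex,
            **flags.as_dict(),
            **{k: round(v, 3) for k, v in subject.true_volumes.as_dict().items()},
            "contrast": contrast,
            "seed": sub_seed,
        }
        rows.append(row)
    manifest = pd.DataFrame(rows)
    if warning:
        manifest.attrs["warning"] = warning

    if output_dir is not None:
        out = Path(output_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths_v, paths_l = [], []
        for sub in subjects:
            vpath = out / f"{sub.subject_id}_{contrast}.nii.gz"
            lpath = out / f"{sub.subject_id}_labels.nii.gz"
            write_volume(sub.volume, vpath)
            write_labelmap(sub.labelmap, lpath)
            sidecar = {
                "landmarks": sub.landmarks.as_dict(),
                "sylvian_seeds_mm": [list(s) for s in sub.sylvian_seeds_mm],
            }
            (out / f"{sub.subject_id}_landmarks.json").write_text(json.dumps(sidecar, indent=2))
            paths_v.append(str(vpath))
            paths_l.append(str(lpath))
        manifest = manifest.assign(volume_path=paths_v, labelmap_path=paths_l)
        if warning:
            manifest.attrs["warning"] = warning
        manifest.to_csv(out / "manifest.csv", index=False)
        if warning:
            (out / "manifest_warning.txt").write_text(warning + "\n")

    return subjects, manifest
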