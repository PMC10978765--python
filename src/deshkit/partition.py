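"""Anatomical-rule partition of the subarachnoid space (SAS).

The high-convexity SAS is delimited by four landmark-derived predicates,
evaluated in world millimetres (so anisotropic grids behave correctly).
A SAS voxel belongs to the high-convexity compartment iff it is

(i)   superior to the top of the bodies of the lateral ventricles
      (an axial z level),
(ii)  within 30 mm perpendicular distance of the midsagittal plane,
(iii) on or posterior to the coronal plane perpendicular to the AC-PC
      line passing through the front edge of the genu of the corpus
      callosum, and
(iv)  anterior to the posterior parts of the callosomarginal sulci
      (a coronal level along the AC-PC direction).

The Sylvian fissure + basal cistern compartment is then extracted from the
remaining SAS as the 26-connected components containing supplied seed
points (a documented stand-in for manual/workstation delineation); whatever
is left is "other SAS".
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage

from deshkit import labels as L
from deshkit.io import LabelMap

__all__ = [
    "Landmarks",
    "CompartmentVolumes",
    "high_convexity_mask",
    "partition_sas",
    "compartment_volumes",
    "LATERAL_BOUND_MM",
]

#: Lateral bound of the high-convexity SAS: 3 cm from the midline.
LATERAL_BOUND_MM = 30.0


@dataclass(frozen=True)
class Landmarks:
    """World-mm landmarks anchoring the high-convexity SAS definition."""

    ac_mm: tuple[float, float, float]
    pc_mm: tuple[float, float, float]
    midsagittal_point_mm: tuple[float, float, float]
    midsagittal_normal: tuple[float, float, float]
    genu_front_mm: tuple[float, float, float]
    ventricle_body_top_z_mm: float
    callosomarginal_posterior_mm: float

    def __post_init__(self) -> None:
        ac = np.asarray(self.ac_mm, dtype=float)
        pc = np.asarray(self.pc_mm, dtype=float)
        if np.allclose(ac, pc):
            raise ValueError("degenerate AC-PC line: AC equals PC")
        n = np.asarray(self.midsagittal_normal, dtype=float)
        if not np.isclose(np.linalg.norm(n), 1.0, atol=1e-6):
            raise ValueError("midsagittal normal must be unit length")

    @property
    def acpc_direction(self) -> np.ndarray:
        """Unit vector from PC to AC (pointing anterior)."""
        d = np.asarray(self.ac_mm, dtype=float) - np.asarray(self.pc_mm, dtype=float)
        return d / np.linalg.norm(d)

    def as_dict(self) -> dict:
        return {
            "ac_mm": list(self.ac_mm),
            "pc_mm": list(self.pc_mm),
            "midsagittal_point_mm": list(self.midsagittal_point_mm),
            "midsagittal_normal": list(self.midsagittal_normal),
            "genu_front_mm": list(self.genu_front_mm),
            "ventricle_body_top_z_mm": self.ventricle_body_top_z_mm,
            "callosomarginal_posterior_mm": self.callosomarginal_posterior_mm,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Landmarks":
        return cls(
            ac_mm=tuple(d["ac_mm"]),
            pc_mm=tuple(d["pc_mm"]),
            midsagittal_point_mm=tuple(d["midsagittal_point_mm"]),
            midsagittal_normal=tuple(d["midsagittal_normal"]),
            genu_front_mm=tuple(d["genu_front_mm"]),
            ventricle_body_top_z_mm=float(d["ventricle_body_top_z_mm"]),
            callosomarginal_posterior_mm=float(d["callosomarginal_posterior_mm"]),
        )


@dataclass(frozen=True)
class CompartmentVolumes:
    """Per-compartment volumes in mL, with derived totals."""

    total_ventricles_ml: float
    sylvian_basal_ml: float
    high_convexity_sas_ml: float
    other_sas_ml: float

    @property
    def total_sas_ml(self) -> float:
        return self.sylvian_basal_ml + self.high_convexity_sas_ml + self.other_sas_ml

    @property
    def intracranial_csf_ml(self) -> float:
        return self.total_sas_ml + self.total_ventricles_ml

    def as_dict(self) -> dict[str, float]:
        return {
            "total_ventricles_ml": self.total_ventricles_ml,
            "sylvian_basal_ml": self.sylvian_basal_ml,
            "high_convexity_sas_ml": self.high_convexity_sas_ml,
            "other_sas_ml": self.other_sas_ml,
            "total_sas_ml": self.total_sas_ml,
            "intracranial_csf_ml": self.intracranial_csf_ml,
        }


def _world_grids(shape, voxel_size_mm, origin_mm):
    axes = [origin_mm[i] + voxel_size_mm[i] * np.arange(shape[i]) for i in range(3)]
    return np.meshgrid(*axes, indexing="ij", sparse=True)


def high_convexity_rule(
    shape: tuple[int, int, int],
    lm: Landmarks,
    voxel_size_mm: Sequence[float],
    origin_mm: Sequence[float] = (0.0, 0.0, 0.0),
    lateral_bound_mm: float = LATERAL_BOUND_MM,
) -> np.ndarray:
    """Boolean grid of the four landmark predicates (independent of any mask)."""
    xs, ys, zs = _world_grids(shape, voxel_size_mm, origin_mm)
    d = lm.acpc_direction

    # (i) superior to the lateral-ventricle body top
    above = zs >= lm.ventricle_body_top_z_mm
    # (ii) perpendicular distance to the midsagittal plane <= 30 mm
    n = np.asarray(lm.midsagittal_normal, dtype=float)
    p0 = np.asarray(lm.midsagittal_point_mm, dtype=float)
    dist = np.abs((xs - p0[0]) * n[0] + (ys - p0[1]) * n[1] + (zs - p0[2]) * n[2])
    medial = dist <= lateral_bound_mm
    # (iii) on or posterior to the genu-front coronal plane (normal along AC-PC)
    g = np.asarray(lm.genu_front_mm, dtype=float)
    along = xs * d[0] + ys * d[1] + zs * d[2]
    posterior_to_genu = along <= float(g @ d) + 1e-9
    # (iv) anterior to the posterior callosomarginal level (same axis)
    anterior_to_cm = along >= lm.callosomarginal_posterior_mm - 1e-9

    return above & medial & posterior_to_genu & anterior_to_cm


def high_convexity_mask(
    sas: np.ndarray,
    lm: Landmarks,
    voxel_size_mm: Sequence[float],
    origin_mm: Sequence[float] = (0.0, 0.0, 0.0),
    lateral_bound_mm: float = LATERAL_BOUND_MM,
) -> np.ndarray:
    """SAS voxels satisfying all four high-convexity predicates."""
    sas = np.asarray(sas, dtype=bool)
    rule = high_convexity_rule(sas.shape, lm, voxel_size_mm, origin_mm, lateral_bound_mm)
    return sas & rule


def _seed_to_index(seed_mm, shape, voxel_size_mm, origin_mm):
    idx = tuple(
        int(round((seed_mm[i] - origin_mm[i]) / voxel_size_mm[i])) for i in range(3)
    )
    if any(not (0 <= idx[i] < shape[i]) for i in range(3)):
        raise ValueError(f"seed {tuple(seed_mm)} mm falls outside the grid")
    return idx


def partition_sas(
    sas: np.ndarray,
    sylvian_seeds: Sequence[Sequence[float]],
    lm: Landmarks,
    voxel_size_mm: Sequence[float],
    origin_mm: Sequence[float] = (0.0, 0.0, 0.0),
) -> LabelMap:
    """Partition a binary SAS mask into its three compartments.

    Returns a :class:`LabelMap` over the shared code table in which SAS
    voxels carry ``SYLVIAN_BASAL``, ``HIGH_CONVEXITY_SAS`` or ``OTHER_SAS``
    and everything else is ``BACKGROUND``.  The three compartments are
    disjoint and their union is exactly the input mask.
    """
    sas = np.asarray(sas, dtype=bool)
    hc = high_convexity_mask(sas, lm, voxel_size_mm, origin_mm)
    rest = sas & ~hc

    out = np.zeros(sas.shape, dtype=np.uint8)
    out[hc] = L.HIGH_CONVEXITY_SAS

    if sas.any():
        structure = np.ones((3, 3, 3), dtype=bool)  # 26-connectivity
        comp, _ = ndimage.label(rest, structure=structure)
        sylvian_ids = set()
        for seed in sylvian_seeds:
            idx = _seed_to_index(seed, sas.shape, voxel_size_mm, origin_mm)
            if not sas[idx]:
                raise ValueError(f"sylvian seed {tuple(float(s) for s in seed)} mm is outside the SAS mask")
            if rest[idx]:
                sylvian_ids.add(int(comp[idx]))
        if sylvian_ids:
            sylvian = np.isin(comp, sorted(sylvian_ids))
            out[sylvian] = L.SYLVIAN_BASAL
        out[rest & (out == 0)] = L.OTHER_SAS
    elif sylvian_seeds:
        raise ValueError("sylvian seeds supplied for an empty SAS mask")

    return LabelMap(out, tuple(float(s) for s in voxel_size_mm), tuple(float(o) for o in origin_mm),
                    categories=L.CATEGORIES)


def compartment_volumes(labels: LabelMap, voxel_size_mm: Sequence[float] | None = None) -> CompartmentVolumes:
    """Count voxels per compartment code and convert to mL."""
    if voxel_size_mm is None:
        voxel_size_mm = labels.voxel_size_mm
    data = labels.data
    present = set(int(c) for c in np.unique(data))
    if not present.issubset(set(L.CATEGORIES)):
        raise ValueError(f"unknown label codes {sorted(present - set(L.CATEGORIES))}")
    vox_ml = float(np.prod(voxel_size_mm)) / 1000.0
    count = lambda c: float(np.count_nonzero(data == c))
    return CompartmentVolumes(
        total_ventricles_ml=count(L.VENTRICLES) * vox_ml,
        sylvian_basal_ml=count(L.SYLVIAN_BASAL) * vox_ml,
        high_convexity_sas_ml=count(L.HIGH_CONVEXITY_SAS) * vox_ml,
        other_sas_ml=count(L.OTHER_SAS) * vox_ml,
    )
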