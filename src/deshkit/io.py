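"""Volumes, label maps, NIfTI round trips, run configuration and seeding.

Conventions (fixed and tested):

* World coordinates are millimetres in an RAS-like frame: +x right,
  +y anterior, +z superior.  Voxel indices are 0-based; voxel ``(0, 0, 0)``
  sits at ``origin_mm`` and axis ``i`` advances by ``voxel_size_mm[i]``.
* Label maps are written with an unsigned 8-bit datatype using the shared
  code table in :mod:`deshkit.labels`.
* All randomness flows from one top-level integer seed through named
  substreams (see :func:`substream`).
"""

from __future__ import annotations

import hashlib
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import nibabel as nib
import numpy as np
import yaml

__all__ = [
    "Volume",
    "LabelMap",
    "read_volume",
    "write_volume",
    "read_labelmap",
    "write_labelmap",
    "RunConfig",
    "load_run_config",
    "substream",
    "provenance_record",
]


@dataclass
class Volume:
    """A 3D scalar intensity grid with voxel spacing and world origin."""

    data: np.ndarray
    voxel_size_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"Volume data must be 3D, got {self.data.ndim}D")
        self.voxel_size_mm = tuple(float(s) for s in self.voxel_size_mm)
        self.origin_mm = tuple(float(o) for o in self.origin_mm)
        if len(self.voxel_size_mm) != 3 or any(s <= 0 for s in self.voxel_size_mm):
            raise ValueError(f"voxel spacing must be 3 positive values, got {self.voxel_size_mm}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("Volume intensities must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_size_mm))

    def world_coordinates(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Open (broadcastable) world-mm coordinate grids along each axis."""
        axes = [
            self.origin_mm[i] + self.voxel_size_mm[i] * np.arange(self.shape[i])
            for i in range(3)
        ]
        return tuple(np.meshgrid(*axes, indexing="ij", sparse=True))  # type: ignore[return-value]


@dataclass
class LabelMap:
    """A 3D integer category grid sharing the Volume grid conventions."""

    data: np.ndarray
    voxel_size_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    categories: tuple[int, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim != 3:
            raise ValueError(f"LabelMap data must be 3D, got {arr.ndim}D")
        if not np.issubdtype(arr.dtype, np.integer):
            rounded = np.rint(arr)
            if not np.all(np.abs(arr - rounded) <= 1e-6):
                bad = arr[np.abs(arr - rounded) > 1e-6].flat[0]
                raise ValueError(f"non-integer label value {bad!r}")
            arr = rounded.astype(np.uint8)
        self.data = arr.astype(np.uint8, copy=False)
        self.voxel_size_mm = tuple(float(s) for s in self.voxel_size_mm)
        self.origin_mm = tuple(float(o) for o in self.origin_mm)
        if any(s <= 0 for s in self.voxel_size_mm):
            raise ValueError(f"voxel spacing must be positive, got {self.voxel_size_mm}")
        if not self.categories:
            self.categories = tuple(int(c) for c in np.unique(self.data))
        else:
            self.categories = tuple(int(c) for c in self.categories)
            present = set(int(c) for c in np.unique(self.data))
            if not present.issubset(self.categories):
                raise ValueError(
                    f"label codes {sorted(present - set(self.categories))} "
                    f"not in category table {self.categories}"
                )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_size_mm))

    def mask(self, *codes: int) -> np.ndarray:
        """Boolean mask of voxels carrying any of the given codes."""
        return np.isin(self.data, list(codes))

    def world_coordinates(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return Volume.world_coordinates(self)  # type: ignore[arg-type]


def _affine(voxel_size_mm, origin_mm) -> np.ndarray:
    aff = np.eye(4)
    aff[:3, :3] = np.diag(voxel_size_mm)
    aff[:3, 3] = origin_mm
    return aff


def _grid_from_img(img: nib.Nifti1Image) -> tuple[tuple, tuple]:
    zooms = img.header.get_zooms()[:3]
    if any(z <= 0 for z in zooms):
        raise ValueError(f"missing or non-positive voxel spacing {zooms}")
    origin = tuple(float(v) for v in img.affine[:3, 3])
    return tuple(float(z) for z in zooms), origin


def read_volume(path: str | Path) -> Volume:
    """Read a 3D scalar NIfTI volume.

    Raises ``ValueError`` for non-3D images or missing spacing.
    """
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D image, got {data.ndim}D")
    spacing, origin = _grid_from_img(img)
    return Volume(np.asarray(data, dtype=np.float32), spacing, origin)


def write_volume(v: Volume, path: str | Path) -> None:
    img = nib.Nifti1Image(np.asarray(v.data, dtype=np.float32), _affine(v.voxel_size_mm, v.origin_mm))
    img.header.set_zooms(v.voxel_size_mm)
    nib.save(img, str(path))


def read_labelmap(path: str | Path) -> LabelMap:
    """Read an integer label map; near-integers (tol 1e-6) are rounded."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D label map, got {data.ndim}D")
    spacing, origin = _grid_from_img(img)
    return LabelMap(data, spacing, origin)


def write_labelmap(m: LabelMap, path: str | Path) -> None:
    img = nib.Nifti1Image(m.data.astype(np.uint8), _affine(m.voxel_size_mm, m.origin_mm))
    img.header.set_zooms(m.voxel_size_mm)
    nib.save(img, str(path))


# ---------------------------------------------------------------------------
# Run configuration


_CONFIG_DEFAULTS: dict[str, Any] = {
    "seed": 0,
    "grid_shape": [64, 64, 64],
    "voxel_size_mm": [2.5, 2.5, 2.5],
    "contrast": "T2_like",
    "noise_sd": 20.0,
    "cohort_size": 60,
    "desh_fraction": 0.3,
    "split_fractions": [0.70, 0.19, 0.11],
    "pathway": "oracle",  # "oracle" (ground-truth labels) or "unet"
    "seg_iterations": 300,
    "seg_base_channels": 8,
    "clf_iterations": 120,
    "clf_batch_size": 4,
    "n_boot": 500,
    "augment": True,
    "output_dir": "runs/default",
}


@dataclass(frozen=True)
class RunConfig:
    """Validated, fully-defaulted pipeline configuration."""

    values: Mapping[str, Any]

    def __getitem__(self, key: str) -> Any:
        return self.values[key]

    def hash(self) -> str:
        blob = json.dumps(dict(self.values), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def load_run_config(path: str | Path | None = None, overrides: Mapping[str, Any] | None = None) -> RunConfig:
    """Load a YAML/JSON run configuration, filling defaults.

    Unknown keys are rejected with the accepted key list in the message; an
    empty file yields the documented defaults (seed 0).
    """
    cfg = dict(_CONFIG_DEFAULTS)
    user: dict[str, Any] = {}
    if path is not None:
        text = Path(path).read_text()
        loaded = yaml.safe_load(text)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ValueError(f"{path}: config must be a mapping")
        user.update(loaded)
    if overrides:
        user.update(overrides)
    unknown = sorted(set(user) - set(cfg))
    if unknown:
        raise ValueError(
            f"unknown config keys {unknown}; accepted keys: {sorted(cfg)}"
        )
    cfg.update(user)
    # a scalar voxel size means isotropic spacing
    v = cfg["voxel_size_mm"]
    if np.isscalar(v):
        cfg["voxel_size_mm"] = [float(v)] * 3
    return RunConfig(values=cfg)


# ---------------------------------------------------------------------------
# Seeding and provenance


def substream(seed: int, name: str) -> np.random.Generator:
    """Named, reproducible child random stream of one top-level seed.

    Distinct names ("phantom", "augmentation", "training", "bootstrap", ...)
    give statistically independent generators; the same (seed, name) pair
    always returns an identical stream.
    """
    key = zlib.crc32(name.encode()) & 0x7FFFFFFF
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed) & 0x7FFFFFFF, spawn_key=(key,)))


def provenance_record(config: RunConfig, extra: Mapping[str, Any] | None = None) -> dict[str, Any]:
    """Provenance block written alongside every pipeline run."""
    from deshkit import __version__

    rec = {
        "package": "deshkit",
        "version": __version__,
        "config_hash": config.hash(),
        "seed": config["seed"],
        "config": dict(config.values),
    }
    if extra:
        rec.update(extra)
    return rec


def write_provenance(config: RunConfig, path: str | Path, extra: Mapping[str, Any] | None = None) -> None:
    Path(path).write_text(json.dumps(provenance_record(config, extra), indent=2, default=str))
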