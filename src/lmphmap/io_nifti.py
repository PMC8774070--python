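"""NIfTI input/output and voxel-grid bookkeeping.

All per-patient volumes (weighted images, lesion masks, PET tumor-to-normal
ratio, optional relaxation-time maps) are exchanged as NIfTI-1/2 files that
must already live on one shared voxel grid: the pipeline performs no
registration or resampling. Masks are stored as uint8, scalar volumes as
float32. Internal coordinates are 0-based voxel indices; world coordinates
exist only through the affine.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, fields
from pathlib import Path
from typing import Mapping

import nibabel as nib
import numpy as np
import yaml

from .errors import ConfigurationError, GridMismatchError

log = logging.getLogger(__name__)

#: absolute tolerance for affine agreement between "compatible" grids
AFFINE_ATOL = 1e-4

#: manifest roles that must be present for every patient
REQUIRED_ROLES = ("t1w", "t2w", "ce_mask", "flair_mask", "tn_ratio")

#: optional manifest roles
OPTIONAL_ROLES = ("eye_mask", "muscle_mask", "t1_relax", "t2_relax")

_MASK_ROLES = frozenset({"ce_mask", "flair_mask", "eye_mask", "muscle_mask"})


@dataclass(frozen=True)
class VolumeGrid:
    """Shape, voxel size and voxel-to-world affine shared by a patient's volumes."""

    shape: tuple[int, int, int]
    voxel_size: tuple[float, float, float]
    affine: np.ndarray

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(s < 1 for s in self.shape):
            raise ConfigurationError(f"grid shape must be a positive integer triple, got {self.shape}")
        if any(v <= 0 for v in self.voxel_size):
            raise ConfigurationError(f"voxel sizes must be positive, got {self.voxel_size}")

    def compatible_with(self, other: "VolumeGrid") -> bool:
        return self.shape == other.shape and np.allclose(
            self.affine, other.affine, atol=AFFINE_ATOL, rtol=0.0
        )

    @classmethod
    def from_image(cls, img: nib.spatialimages.SpatialImage) -> "VolumeGrid":
        zooms = img.header.get_zooms()[:3]
        return cls(
            shape=tuple(int(s) for s in img.shape[:3]),
            voxel_size=tuple(float(z) for z in zooms),
            affine=np.asarray(img.affine, dtype=float),
        )


@dataclass
class PatientVolumeSet:
    """All co-registered volumes and masks of one patient on one grid.

    ``t1w``/``t2w`` carry arbitrary scanner intensity units; ``tn_ratio`` is
    the unitless PET tumor-to-normal ratio; masks are {0,1} uint8 arrays;
    relaxation maps are in milliseconds.
    """

    patient_id: str
    t1w: np.ndarray
    t2w: np.ndarray
    ce_mask: np.ndarray
    flair_mask: np.ndarray
    tn_ratio: np.ndarray
    grid: VolumeGrid
    eye_mask: np.ndarray | None = None
    muscle_mask: np.ndarray | None = None
    t1_relax: np.ndarray | None = None
    t2_relax: np.ndarray | None = None

    def __post_init__(self) -> None:
        for f in fields(self):
            vol = getattr(self, f.name)
            if not isinstance(vol, np.ndarray) or f.name in ("grid", "patient_id"):
                continue
            if tuple(vol.shape) != self.grid.shape:
                raise GridMismatchError(
                    f"patient {self.patient_id}: volume '{f.name}' has shape "
                    f"{tuple(vol.shape)}, expected {self.grid.shape}"
                )
        for name in ("ce_mask", "flair_mask", "eye_mask", "muscle_mask"):
            m = getattr(self, name)
            if m is not None and not np.isin(m, (0, 1)).all():
                raise ConfigurationError(f"mask '{name}' contains values outside {{0,1}}")


def _binarize_mask(data: np.ndarray, *, name: str) -> np.ndarray:
    """Threshold a mask volume at > 0.5, warning when non-{0,1} values occur.

    Upstream registration can interpolate binary masks to fractional values;
    that is a data-quality warning, not an error.
    """
    out = (data > 0.5).astype(np.uint8)
    exotic = np.unique(data[~np.isin(data, (0, 1))])
    if exotic.size:
        log.warning("mask '%s' contained non-binary values %s; binarized at > 0.5", name, exotic[:5])
    return out


def read_volume(path: str | Path) -> tuple[np.ndarray, VolumeGrid]:
    """Read one NIfTI scalar volume as float64 with its grid."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise GridMismatchError(f"{path}: expected a 3D volume, got shape {data.shape}")
    return data, VolumeGrid.from_image(img)


def read_patient(manifest_entry: Mapping[str, str], base_dir: str | Path | None = None) -> PatientVolumeSet:
    """Load one patient's volumes from a role → path mapping.

    ``manifest_entry`` must carry a ``patient_id`` and paths for the five
    required roles (t1w, t2w, ce_mask, flair_mask, tn_ratio); the optional
    roles are loaded when present. All volumes are checked for grid
    compatibility (identical shape, affines within ``AFFINE_ATOL``).
    """
    entry = dict(manifest_entry)
    patient_id = str(entry.pop("patient_id", "") or "")
    if not patient_id:
        raise ConfigurationError("manifest entry lacks a patient_id")
    for role in REQUIRED_ROLES:
        if role not in entry:
            raise ConfigurationError(f"patient {patient_id}: manifest missing required role '{role}'")

    base = Path(base_dir) if base_dir is not None else None

    def _resolve(p: str) -> Path:
        path = Path(p)
        if base is not None and not path.is_absolute():
            path = base / path
        if not path.exists():
            raise ConfigurationError(f"patient {patient_id}: file not found: {path}")
        return path

    volumes: dict[str, np.ndarray] = {}
    grid: VolumeGrid | None = None
    for role in (*REQUIRED_ROLES, *OPTIONAL_ROLES):
        if role not in entry:
            continue
        data, vgrid = read_volume(_resolve(entry[role]))
        if grid is None:
            grid = vgrid
        elif not grid.compatible_with(vgrid):
            raise GridMismatchError(
                f"patient {patient_id}: volume '{role}' is on an incompatible grid "
                f"(shape {vgrid.shape} vs {grid.shape}, or affine mismatch > {AFFINE_ATOL})"
            )
        if role in _MASK_ROLES:
            data = _binarize_mask(data, name=f"{patient_id}/{role}")
        volumes[role] = data

    assert grid is not None
    return PatientVolumeSet(patient_id=patient_id, grid=grid, **volumes)


def write_volume(volume: np.ndarray, grid: VolumeGrid, path: str | Path) -> None:
    """Write a scalar volume as float32 NIfTI (masks as uint8) on ``grid``."""
    volume = np.asarray(volume)
    if tuple(volume.shape) != grid.shape:
        raise GridMismatchError(f"volume shape {tuple(volume.shape)} does not match grid {grid.shape}")
    if volume.dtype == np.uint8 or (
        volume.dtype.kind in "iub" and np.isin(volume, (0, 1)).all()
    ):
        data = volume.astype(np.uint8)
    else:
        data = volume.astype(np.float32)
    img = nib.Nifti1Image(data, grid.affine)
    img.header.set_zooms(grid.voxel_size)
    try:
        nib.save(img, str(path))
    except OSError as exc:  # pragma: no cover - filesystem dependent
        raise IOError(f"cannot write volume to {path}: {exc}") from exc


def load_manifest(path: str | Path) -> list[dict[str, str]]:
    """Read a cohort manifest (YAML or JSON) into a list of role → path entries.

    The manifest is a mapping with a ``patients`` list; relative paths are
    interpreted relative to the manifest's directory and returned resolved.
    """
    path = Path(path)
    text = path.read_text()
    doc = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(doc, dict) or "patients" not in doc:
        raise ConfigurationError(f"{path}: manifest must be a mapping with a 'patients' list")
    entries = []
    for raw in doc["patients"]:
        entry = dict(raw)
        for role in (*REQUIRED_ROLES, *OPTIONAL_ROLES):
            if role in entry:
                p = Path(entry[role])
                entry[role] = str(p if p.is_absolute() else path.parent / p)
        entries.append(entry)
    return entries


def read_cohort(manifest_path: str | Path) -> list[PatientVolumeSet]:
    """Load every patient listed in a cohort manifest."""
    return [read_patient(e) for e in load_manifest(manifest_path)]
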