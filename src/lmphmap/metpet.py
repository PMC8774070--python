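"""Met-PET tumor-to-normal (T/N) ratio computation and high/low segmentation.

A voxel is "Met-PET high" when its T/N ratio strictly exceeds 1.5 — the
cut-off corresponding to high glioma cell density in stereotactic-biopsy
studies. A precomputed T/N volume may be supplied directly; otherwise the
ratio is formed against the mean activity of a user-supplied normal-brain
reference mask (typically contralateral normal brain).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, GridMismatchError, NormalReferenceError

#: T/N cut-off separating Met-PET high from low voxels
DEFAULT_TN_THRESHOLD = 1.5


@dataclass(frozen=True)
class TNConfig:
    """Threshold and normal-reference policy for T/N segmentation."""

    threshold: float = DEFAULT_TN_THRESHOLD
    normal_reference: str = "precomputed"  # or "normal_mask"

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise ConfigurationError(f"T/N threshold must be > 0, got {self.threshold}")
        if self.normal_reference not in ("precomputed", "normal_mask"):
            raise ConfigurationError(
                f"normal_reference must be 'precomputed' or 'normal_mask', got {self.normal_reference!r}"
            )


def compute_tn_volume(pet: np.ndarray, normal_mask: np.ndarray) -> np.ndarray:
    """Voxel-wise PET activity divided by mean activity over the normal mask."""
    pet = np.asarray(pet, dtype=float)
    normal_mask = np.asarray(normal_mask)
    if pet.shape != normal_mask.shape:
        raise GridMismatchError(
            f"PET shape {pet.shape} != normal mask shape {normal_mask.shape}"
        )
    inside = normal_mask > 0
    if not inside.any():
        raise NormalReferenceError("normal-tissue mask is empty")
    mean_normal = float(pet[inside].mean())
    if not np.isfinite(mean_normal) or mean_normal <= 0:
        raise NormalReferenceError(
            f"mean normal-tissue activity must be positive and finite, got {mean_normal}"
        )
    return pet / mean_normal


def segment_high_low(tn: np.ndarray, threshold: float = DEFAULT_TN_THRESHOLD) -> np.ndarray:
    """1 where T/N strictly exceeds the threshold, else 0.

    The inequality is strict: a voxel at exactly the threshold is "low".
    """
    return (np.asarray(tn) > threshold).astype(np.uint8)
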