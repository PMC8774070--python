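"""Non-enhancing-tumor VOI construction and per-voxel table extraction.

The analysis domain is the set of voxels inside the T2-FLAIR hyperintense
lesion but outside the contrast-enhancing lesion — non-enhancing tumor plus
edema. Every downstream statistic is computed on flat per-voxel records
(`VoxelTable`) pulled from these VOIs.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import GridMismatchError
from .io_nifti import PatientVolumeSet
from .metpet import DEFAULT_TN_THRESHOLD, segment_high_low

log = logging.getLogger(__name__)

#: column order of a VoxelTable CSV; voxel_index_{0,1,2} are 0-based indices
VOXEL_TABLE_COLUMNS = (
    "patient_id",
    "voxel_index_0",
    "voxel_index_1",
    "voxel_index_2",
    "rt1t2",
    "tn",
    "met_class",
    "t1_relax_ms",
    "t2_relax_ms",
)


def define_voi(flair_mask: np.ndarray, ce_mask: np.ndarray) -> np.ndarray:
    """FLAIR hyperintense lesion minus the contrast-enhancing lesion.

    Output voxel is 1 iff the FLAIR mask is 1 and the CE mask is 0, so
    ``|VOI| = |FLAIR| - |FLAIR AND CE|`` exactly. An empty FLAIR mask yields
    an empty VOI with a warning (a patient without measurable lesion burden),
    not an error.
    """
    flair_mask = np.asarray(flair_mask)
    ce_mask = np.asarray(ce_mask)
    if flair_mask.shape != ce_mask.shape:
        raise GridMismatchError(
            f"FLAIR mask shape {flair_mask.shape} != CE mask shape {ce_mask.shape}"
        )
    if not flair_mask.any():
        log.warning("empty FLAIR mask: VOI is empty")
    voi = ((flair_mask > 0) & ~(ce_mask > 0)).astype(np.uint8)
    if flair_mask.any() and not voi.any():
        log.warning("FLAIR lesion entirely contrast-enhancing: VOI is empty")
    return voi


def extract_voxel_table(
    cohort: Iterable[PatientVolumeSet],
    rt1t2_volumes: Sequence[np.ndarray],
    tn_threshold: float = DEFAULT_TN_THRESHOLD,
) -> pd.DataFrame:
    """One row per VOI voxel per patient, labelled Met-PET high/low.

    ``rt1t2_volumes`` are the reconstructed ratio maps, one per patient in
    cohort order. Rows whose rT1/T2 is non-finite or non-positive are dropped
    (they indicate calibration failure, not signal) with a logged count.
    """
    frames = []
    for pvs, rt1t2 in zip(cohort, rt1t2_volumes, strict=True):
        if tuple(rt1t2.shape) != pvs.grid.shape:
            raise GridMismatchError(
                f"patient {pvs.patient_id}: ratio map shape {rt1t2.shape} != grid {pvs.grid.shape}"
            )
        voi = define_voi(pvs.flair_mask, pvs.ce_mask)
        idx = np.argwhere(voi > 0)
        if idx.size == 0:
            continue
        sel = tuple(idx.T)
        r = rt1t2[sel]
        tn = pvs.tn_ratio[sel]
        keep = np.isfinite(r) & (r > 0)
        dropped = int((~keep).sum())
        if dropped:
            log.info("patient %s: dropped %d VOI voxels with non-finite/non-positive rT1/T2",
                     pvs.patient_id, dropped)
        high = segment_high_low(tn[keep], tn_threshold).astype(bool)
        frame = pd.DataFrame(
            {
                "patient_id": pvs.patient_id,
                "voxel_index_0": idx[keep, 0],
                "voxel_index_1": idx[keep, 1],
                "voxel_index_2": idx[keep, 2],
                "rt1t2": r[keep],
                "tn": tn[keep],
                "met_class": np.where(high, "high", "low"),
                "t1_relax_ms": pvs.t1_relax[sel][keep] if pvs.t1_relax is not None else np.nan,
                "t2_relax_ms": pvs.t2_relax[sel][keep] if pvs.t2_relax is not None else np.nan,
            }
        )
        frames.append(frame)
    if not frames:
        return pd.DataFrame(columns=list(VOXEL_TABLE_COLUMNS))
    table = pd.concat(frames, ignore_index=True)
    return table[list(VOXEL_TABLE_COLUMNS)]
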