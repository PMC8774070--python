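"""Leave-one-patient-out (LOPO) validation of LMPH as a voxel classifier.

For each held-out patient the conversion table is learned from all other
patients' VOI voxels, the held-out rT1/T2 values are converted to LMPH
scores, and the scores are tested against the patient's own Met-PET
high/low labels with a ROC curve. Per-patient AUCs are summarized as
mean ± SD with a two-sided one-sample t-test against chance (0.5).

AUC follows the Mann–Whitney convention, P(score_high > score_low) +
½·P(tie) — ties are guaranteed by the binned scores, and the ½-credit rule
is the unique convention consistent with the trapezoidal ROC area. Patients
whose VOI contains no Met-PET-high voxels (or, symmetrically, no low
voxels) have no defined ROC and are excluded from validation with a
recorded reason; their voxels still contribute to the training folds of
other patients.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve as _sk_roc_curve

from .errors import (
    ClassCoverageError,
    ConfigurationError,
    DegenerateTestError,
    EmptyCVError,
    SampleSizeError,
)
from .io_nifti import PatientVolumeSet
from .lmph import HistogramSpec, build_conversion
from .masks import extract_voxel_table
from .metpet import DEFAULT_TN_THRESHOLD
from .ratiomap import reconstruct_rt1t2

log = logging.getLogger(__name__)

#: fixed false-positive-rate grid for curve averaging across patients
FPR_GRID = np.linspace(0.0, 1.0, 101)


def _as_binary_labels(labels: Sequence) -> np.ndarray:
    arr = np.asarray(labels)
    if arr.dtype.kind in "USO":
        return (arr == "high").astype(int)
    return arr.astype(int)


def roc_auc(scores: Sequence[float], labels: Sequence) -> tuple[tuple[np.ndarray, np.ndarray], float]:
    """ROC curve and area for LMPH scores against high/low labels.

    Returns ``((fpr, tpr), auc)``; higher score predicts "high". The
    trapezoidal area over the thresholded curve equals the Mann–Whitney
    statistic with ½ tie credit.
    """
    y = _as_binary_labels(labels)
    s = np.asarray(scores, dtype=float)
    if s.shape != y.shape:
        raise ConfigurationError(f"scores ({s.shape}) and labels ({y.shape}) differ in length")
    if not np.isfinite(s).all():
        raise ConfigurationError("scores must be finite; exclude invalid voxels first")
    if y.min() == y.max():
        raise ClassCoverageError("both classes must be present to compute a ROC curve")
    fpr, tpr, _ = _sk_roc_curve(y, s, drop_intermediate=False)
    return (fpr, tpr), float(_trapezoid_auc(fpr, tpr))


def one_sample_ttest(values: Sequence[float], mu0: float) -> tuple[float, float]:
    """Classical two-sided one-sample t-test of the mean against ``mu0``."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise SampleSizeError(f"t-test needs at least 2 values, got {values.size}")
    if np.ptp(values) == 0.0:
        raise DegenerateTestError("zero-variance sample; t statistic undefined")
    res = stats.ttest_1samp(values, popmean=mu0, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


@dataclass
class PatientROC:
    """One held-out patient's LMPH scores, labels and ROC on the fixed FPR grid."""

    patient_id: str
    scores: np.ndarray
    labels: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    n_excluded_voxels: int

    @property
    def n_high(self) -> int:
        return int(_as_binary_labels(self.labels).sum())

    @property
    def n_low(self) -> int:
        return int(len(self.labels) - self.n_high)


@dataclass
class CVReport:
    """Cross-validation summary: per-patient ROCs, exclusions and the t-test."""

    per_patient: list[PatientROC]
    excluded_patients: list[tuple[str, str]]
    mean_auc: float
    sd_auc: float
    t_stat: float
    p_value: float
    mean_curve_fpr: np.ndarray = field(default_factory=lambda: FPR_GRID.copy())
    mean_curve_tpr: np.ndarray | None = None
    sd_curve_tpr: np.ndarray | None = None

    def aucs(self) -> np.ndarray:
        return np.array([p.auc for p in self.per_patient])

    def to_frame(self) -> pd.DataFrame:
        """Per-patient AUC table, with excluded patients listed reason-only."""
        rows = [
            {
                "patient_id": p.patient_id,
                "auc": p.auc,
                "n_high": p.n_high,
                "n_low": p.n_low,
                "n_excluded_voxels": p.n_excluded_voxels,
                "excluded_reason": "",
            }
            for p in self.per_patient
        ]
        rows += [
            {
                "patient_id": pid,
                "auc": np.nan,
                "n_high": 0,
                "n_low": 0,
                "n_excluded_voxels": 0,
                "excluded_reason": reason,
            }
            for pid, reason in self.excluded_patients
        ]
        return pd.DataFrame(rows)

    def save_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.10g", na_rep="")

    def save_json(self, path: str | Path) -> None:
        doc = {
            "mean_auc": self.mean_auc,
            "sd_auc": self.sd_auc,
            "t_stat": self.t_stat,
            "p_value": self.p_value,
            "n_patients": len(self.per_patient),
            "excluded_patients": [
                {"patient_id": pid, "reason": reason} for pid, reason in self.excluded_patients
            ],
            "per_patient_auc": {p.patient_id: p.auc for p in self.per_patient},
        }
        Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")


def lopo_cv_from_table(
    table: pd.DataFrame,
    spec: HistogramSpec | None = None,
) -> CVReport:
    """LOPO cross-validation directly on a labelled voxel table.

    For every held-out patient with both classes present, the conversion is
    trained on all remaining patients and the held-out voxels are scored
    through it. Voxels whose LMPH is undefined (empty training bin) or whose
    rT1/T2 lies outside the histogram support are excluded from that
    patient's ROC, with the count recorded.
    """
    spec = spec or HistogramSpec()
    patient_ids = list(pd.unique(table["patient_id"]))
    if len(patient_ids) < 3:
        raise ConfigurationError(f"LOPO needs at least 3 patients, got {len(patient_ids)}")

    per_patient: list[PatientROC] = []
    excluded: list[tuple[str, str]] = []
    for pid in patient_ids:
        held = table[table["patient_id"] == pid]
        n_high = int((held["met_class"] == "high").sum())
        n_low = int(len(held) - n_high)
        if n_high == 0 or n_low == 0:
            reason = "NH=0" if n_high == 0 else "NL=0"
            log.info("patient %s excluded from validation: %s", pid, reason)
            excluded.append((str(pid), reason))
            continue
        train = table[table["patient_id"] != pid]
        conv = build_conversion(train, spec)
        bins = spec.assign_bins(held["rt1t2"].to_numpy(dtype=float))
        scores = np.full(bins.shape, np.nan)
        in_range = bins >= 0
        scores[in_range] = conv.lmph[bins[in_range]]
        keep = np.isfinite(scores)
        n_excl = int((~keep).sum())
        labels = _as_binary_labels(held["met_class"].to_numpy())[keep]
        if labels.size == 0 or labels.min() == labels.max():
            reason = f"single class after exclusions ({n_excl} voxels excluded)"
            log.info("patient %s excluded from validation: %s", pid, reason)
            excluded.append((str(pid), reason))
            continue
        (fpr, tpr), auc_value = roc_auc(scores[keep], labels)
        tpr_grid = np.interp(FPR_GRID, fpr, tpr)
        per_patient.append(
            PatientROC(
                patient_id=str(pid),
                scores=scores[keep],
                labels=labels,
                fpr=FPR_GRID.copy(),
                tpr=tpr_grid,
                auc=auc_value,
                n_excluded_voxels=n_excl,
            )
        )

    if not per_patient:
        raise EmptyCVError("every patient was excluded from cross-validation")

    aucs = np.array([p.auc for p in per_patient])
    if aucs.size >= 2 and np.ptp(aucs) > 0:
        t_stat, p_value = one_sample_ttest(aucs, 0.5)
    else:
        t_stat, p_value = np.nan, np.nan
    curves = np.vstack([p.tpr for p in per_patient])
    return CVReport(
        per_patient=per_patient,
        excluded_patients=excluded,
        mean_auc=float(aucs.mean()),
        sd_auc=float(aucs.std(ddof=1)) if aucs.size > 1 else 0.0,
        t_stat=t_stat,
        p_value=p_value,
        mean_curve_tpr=curves.mean(axis=0),
        sd_curve_tpr=curves.std(axis=0, ddof=1) if len(per_patient) > 1 else np.zeros(FPR_GRID.size),
    )


def lopo_cv(
    cohort: Sequence[PatientVolumeSet],
    spec: HistogramSpec | None = None,
    tn_threshold: float = DEFAULT_TN_THRESHOLD,
) -> CVReport:
    """Full-volume LOPO validation: reconstruct rT1/T2 per patient, then cross-validate.

    Each patient's ratio map is calibrated against their eye/temporal-muscle
    reference regions when those masks are present; otherwise the weighted
    images are taken as pre-calibrated.
    """
    cohort = list(cohort)
    if len(cohort) < 3:
        raise ConfigurationError(f"LOPO needs at least 3 patients, got {len(cohort)}")
    ratio_maps = [
        reconstruct_rt1t2(p.t1w, p.t2w, p.eye_mask, p.muscle_mask) for p in cohort
    ]
    table = extract_voxel_table(cohort, ratio_maps, tn_threshold=tn_threshold)
    return lopo_cv_from_table(table, spec)
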