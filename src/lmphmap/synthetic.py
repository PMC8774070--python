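"""Seeded synthetic GBM cohorts for end-to-end pipeline testing.

Real study data (co-registered MRI, lesion masks and Met-PET of a
34-patient glioblastoma cohort) are not publicly deposited, so this module
generates cohorts with the statistical structure the analysis assumes:

* per patient, VOI voxels carry rT1/T2 values drawn from two overlapping
  truncated-normal class distributions on [0.3, 1.3], with the Met-PET-high
  class narrower than the low class;
* T/N ratios drawn conditionally on class so that the 1.5 cut-off exactly
  reproduces the labels (high: 1.5 + offset + half-normal; low: uniform
  below 1.5);
* relaxation-time covariates tied to rT1/T2 through a decaying-exponential
  law with multiplicative log-normal noise;
* full NIfTI volume sets in which raw T1w/T2w images are constructed so
  that two-reference-peak calibration recovers the sampled rT1/T2 inside a
  synthetic FLAIR ellipsoid with an interior contrast-enhancing core.

Everything is deterministic given the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .errors import ConfigurationError
from .io_nifti import VolumeGrid, write_volume
from .masks import VOXEL_TABLE_COLUMNS

#: cal-space intensity of the T2w image inside the VOI; T1w is this times rT1/T2
_T2_CAL_VOI = 50.0


@dataclass(frozen=True)
class SyntheticCohortConfig:
    """Distributional parameters and seed of a synthetic cohort.

    ``frac_high`` may be a single proportion or one per patient; setting a
    patient's value to 0 creates the NH = 0 exclusion fixture. The
    relaxation links are (amplitude, rate per ms, log-noise sd) per
    relaxation type.
    """

    n_patients: int = 34
    voxels_per_patient: tuple[int, int] = (500, 3000)
    frac_high: float | Sequence[float] = 0.3
    high_dist: tuple[float, float] = (0.9, 0.05)   # (mean, sd) of rT1/T2, Met-PET high
    low_dist: tuple[float, float] = (0.6, 0.15)    # (mean, sd) of rT1/T2, Met-PET low
    ratio_range: tuple[float, float] = (0.3, 1.3)
    t1_relax_link: tuple[float, float, float] = (0.862, -2.13e-5, 0.2)
    t2_relax_link: tuple[float, float, float] = (0.951, -8.84e-4, 0.2)
    tn_high_offset: float = 1e-3                    # strict clearance above the 1.5 cut-off
    tn_high_scale: float = 0.4                      # half-normal scale above the cut-off
    tn_low_range: tuple[float, float] = (0.8, 1.5)
    include_relaxation: bool = True
    grid_shape: tuple[int, int, int] = (32, 32, 32)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ConfigurationError("n_patients must be >= 1")
        lo, hi = self.voxels_per_patient
        if not (1 <= lo <= hi):
            raise ConfigurationError(f"bad voxels_per_patient range {self.voxels_per_patient}")
        for name, (mu, sd) in (("high_dist", self.high_dist), ("low_dist", self.low_dist)):
            if sd <= 0:
                raise ConfigurationError(f"{name} sd must be positive")
            a, b = self.ratio_range
            mass = stats.norm.cdf(b, mu, sd) - stats.norm.cdf(a, mu, sd)
            if mass < 1e-12:
                raise ConfigurationError(
                    f"{name} N({mu}, {sd}) has no mass inside {self.ratio_range}: "
                    "truncation impossible"
                )
        fh = self.frac_high
        for f in np.atleast_1d(fh):
            if not (0.0 <= float(f) < 1.0):
                raise ConfigurationError(f"frac_high values must lie in [0, 1), got {f}")

    def frac_high_for(self, patient_index: int) -> float:
        if np.isscalar(self.frac_high):
            return float(self.frac_high)
        seq = list(self.frac_high)
        if len(seq) != self.n_patients:
            raise ConfigurationError(
                f"frac_high sequence length {len(seq)} != n_patients {self.n_patients}"
            )
        return float(seq[patient_index])


def two_gaussian_auc(high_dist: tuple[float, float], low_dist: tuple[float, float]) -> float:
    """Closed-form ranking probability P(X_high > X_low) for two normals.

    Phi(dmu / sqrt(sd_high^2 + sd_low^2)) — the population AUC of a perfect
    scorer of the two untruncated class distributions.
    """
    dmu = high_dist[0] - low_dist[0]
    return float(stats.norm.cdf(dmu / np.hypot(high_dist[1], low_dist[1])))


def _truncnorm_rvs(mu: float, sd: float, lo: float, hi: float, size: int,
                   rng: np.random.Generator) -> np.ndarray:
    a, b = (lo - mu) / sd, (hi - mu) / sd
    return stats.truncnorm.rvs(a, b, loc=mu, scale=sd, size=size, random_state=rng)


def _sample_patient(
    config: SyntheticCohortConfig, patient_index: int, n_vox: int, rng: np.random.Generator
) -> pd.DataFrame:
    """Draw one patient's per-voxel rT1/T2, T/N and relaxation values."""
    fh = config.frac_high_for(patient_index)
    n_high = int(rng.binomial(n_vox, fh)) if fh > 0 else 0
    n_low = n_vox - n_high
    lo, hi = config.ratio_range
    r = np.concatenate([
        _truncnorm_rvs(*config.high_dist, lo, hi, n_high, rng),
        _truncnorm_rvs(*config.low_dist, lo, hi, n_low, rng),
    ])
    tn = np.concatenate([
        1.5 + config.tn_high_offset + np.abs(rng.normal(0.0, config.tn_high_scale, n_high)),
        rng.uniform(*config.tn_low_range, n_low),
    ])
    met_class = np.array(["high"] * n_high + ["low"] * n_low)

    def _invert_link(link: tuple[float, float, float]) -> np.ndarray:
        a, b, noise_sd = link
        eps = rng.normal(0.0, noise_sd, n_vox)
        return (np.log(r) + eps - np.log(a)) / b

    frame = pd.DataFrame(
        {
            "patient_id": f"p{patient_index:03d}",
            "voxel_index_0": 0,
            "voxel_index_1": 0,
            "voxel_index_2": 0,
            "rt1t2": r,
            "tn": tn,
            "met_class": met_class,
            "t1_relax_ms": _invert_link(config.t1_relax_link)
            if config.include_relaxation else np.nan,
            "t2_relax_ms": _invert_link(config.t2_relax_link)
            if config.include_relaxation else np.nan,
        }
    )
    return frame


def generate_voxel_table(config: SyntheticCohortConfig) -> pd.DataFrame:
    """Sample a cohort voxel table (no volumes) from the configured distributions."""
    rng = np.random.default_rng(config.seed)
    lo, hi = config.voxels_per_patient
    frames = []
    for i in range(config.n_patients):
        n_vox = int(rng.integers(lo, hi + 1))
        frames.append(_sample_patient(config, i, n_vox, rng))
    table = pd.concat(frames, ignore_index=True)
    return table[list(VOXEL_TABLE_COLUMNS)]


# ---------------------------------------------------------------------------
# Volume-level generation
# ---------------------------------------------------------------------------

def _ellipsoid(shape: tuple[int, int, int], center: np.ndarray, semi: np.ndarray) -> np.ndarray:
    grids = np.indices(shape, dtype=float)
    d2 = sum(((g - c) / s) ** 2 for g, c, s in zip(grids, center, semi))
    return (d2 <= 1.0).astype(np.uint8)


def _sphere(shape: tuple[int, int, int], center: tuple[float, ...], radius: float) -> np.ndarray:
    return _ellipsoid(shape, np.asarray(center, float), np.full(3, float(radius)))


def generate_volume_cohort(config: SyntheticCohortConfig, out_dir: str | Path) -> Path:
    """Write a full synthetic NIfTI cohort and return the manifest path.

    Per patient: a FLAIR ellipsoid with an interior contrast-enhancing
    core, constant-intensity eye and temporal-muscle reference spheres, raw
    T1w/T2w images built as per-image affine distortions (random scanner
    gain/offset) of cal-space images whose ratio inside the VOI equals the
    sampled rT1/T2, a precomputed T/N volume, optional relaxation maps, a
    ground-truth voxel CSV and a YAML manifest consumable by the reader.

    The per-patient VOI voxel count is dictated by the sampled lesion
    geometry on the configured grid (``voxels_per_patient`` applies to the
    table-level generator).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    shape = tuple(config.grid_shape)
    if min(shape) < 24:
        raise ConfigurationError(f"grid {shape} too small for lesion + reference geometry")
    grid = VolumeGrid(shape=shape, voxel_size=(1.0, 1.0, 1.0), affine=np.eye(4))

    manifest_entries = []
    truth_frames = []
    for i in range(config.n_patients):
        pid = f"p{i:03d}"
        pdir = out_dir / pid
        pdir.mkdir(exist_ok=True)

        center = np.array(shape, float) / 2.0 + rng.uniform(-2, 2, 3)
        semi = rng.uniform(0.22, 0.30, 3) * np.array(shape, float)
        flair = _ellipsoid(shape, center, semi)
        ce = _ellipsoid(shape, center + rng.uniform(-1, 1, 3), semi * rng.uniform(0.35, 0.5, 3))
        eye = _sphere(shape, (4.0, 4.0, 4.0), 2.5)
        muscle = _sphere(shape, (shape[0] - 5.0, shape[1] - 5.0, shape[2] - 5.0), 2.5)
        # keep lesion masks clear of the reference regions so the VOI is exactly FLAIR \ CE
        references = (eye > 0) | (muscle > 0)
        flair[references] = 0
        ce[references] = 0
        voi = (flair > 0) & ~(ce > 0)
        idx = np.argwhere(voi)
        n_vox = len(idx)
        if n_vox < 10:
            raise ConfigurationError(f"patient {pid}: degenerate lesion geometry ({n_vox} VOI voxels)")

        sample = _sample_patient(config, i, n_vox, rng)
        sample[["voxel_index_0", "voxel_index_1", "voxel_index_2"]] = idx
        truth_frames.append(sample)

        sel = tuple(idx.T)
        r = sample["rt1t2"].to_numpy()

        t1_cal = np.full(shape, 60.0)
        t2_cal = np.full(shape, 40.0)
        ce_only = (ce > 0) & ~(eye > 0) & ~(muscle > 0)
        t1_cal[ce_only], t2_cal[ce_only] = 70.0, 35.0
        t1_cal[sel] = _T2_CAL_VOI * r
        t2_cal[sel] = _T2_CAL_VOI
        for img in (t1_cal, t2_cal):
            img[eye > 0] = 0.0      # low reference peak: exactly the calibration target
            img[muscle > 0] = 100.0  # high reference peak

        gain1, gain2 = rng.uniform(0.5, 2.0, 2)
        offset1, offset2 = rng.uniform(-20.0, 50.0, 2)
        t1_raw = gain1 * t1_cal + offset1
        t2_raw = gain2 * t2_cal + offset2

        tn = np.full(shape, 1.0)
        tn[ce_only] = 2.0
        tn[sel] = sample["tn"].to_numpy()

        paths = {
            "t1w": t1_raw, "t2w": t2_raw,
            "ce_mask": ce, "flair_mask": flair,
            "tn_ratio": tn, "eye_mask": eye, "muscle_mask": muscle,
        }
        if config.include_relaxation:
            t1_relax = np.full(shape, 1000.0)
            t2_relax = np.full(shape, 80.0)
            t1_relax[sel] = sample["t1_relax_ms"].to_numpy()
            t2_relax[sel] = sample["t2_relax_ms"].to_numpy()
            paths["t1_relax"] = t1_relax
            paths["t2_relax"] = t2_relax

        entry = {"patient_id": pid}
        for role, volume in paths.items():
            fname = f"{pid}/{role}.nii.gz"
            write_volume(volume, grid, out_dir / fname)
            entry[role] = fname
        manifest_entries.append(entry)

    truth = pd.concat(truth_frames, ignore_index=True)[list(VOXEL_TABLE_COLUMNS)]
    truth.to_csv(out_dir / "ground_truth.csv", index=False, float_format="%.10g")

    manifest_path = out_dir / "manifest.yaml"
    manifest_path.write_text(
        yaml.safe_dump({"patients": manifest_entries}, sort_keys=False)
    )
    return manifest_path


def null_config(**overrides) -> SyntheticCohortConfig:
    """A no-signal cohort: both classes share the low-class rT1/T2 distribution."""
    base = SyntheticCohortConfig(**overrides)
    return replace(base, high_dist=base.low_dist)
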