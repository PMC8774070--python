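"""T1w/T2w-ratio (rT1/T2) map reconstruction.

Weighted MR intensities are in arbitrary, scanner-dependent units; dividing
them only carries information after both images are put on a common scale.
Each image is calibrated by a two-point affine intensity map that sends the
modal intensity of the eye (vitreous; the low reference) and of the temporal
muscle (the high reference) to fixed standard values. The calibrated ratio
map is then invariant to any per-image gain and offset, which is what makes
rT1/T2 comparable across scanners without further harmonization. The actual
target values are arbitrary: changing them rescales the ratio map by a
global monotone transform, which downstream histogram binning absorbs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, DegenerateCalibrationError, GridMismatchError

#: standard values the reference peaks are mapped to (arbitrary units)
DEFAULT_TARGET_LOW = 0.0
DEFAULT_TARGET_HIGH = 100.0

#: epsilon, as a fraction of target_high, below which the T2w denominator is treated as zero
DEFAULT_EPSILON_FRACTION = 1e-6


@dataclass(frozen=True)
class CalibrationResult:
    """Parameters of the fitted two-point affine intensity map."""

    slope: float
    intercept: float
    ref_low_peak: float
    ref_high_peak: float
    target_low: float
    target_high: float


def find_reference_peak(image: np.ndarray, region_mask: np.ndarray) -> float:
    """Modal intensity of ``image`` inside ``region_mask``.

    The mode is estimated from a histogram with Freedman–Diaconis bin width,
    refined by parabolic interpolation of the counts around the argmax bin —
    deterministic and robust across sample sizes. A constant in-mask sample
    (zero spread) returns that value directly.
    """
    image = np.asarray(image, dtype=float)
    region_mask = np.asarray(region_mask)
    if image.shape != region_mask.shape:
        raise GridMismatchError(f"image shape {image.shape} != mask shape {region_mask.shape}")
    values = image[region_mask > 0]
    if values.size == 0:
        raise ConfigurationError("reference-region mask is empty")
    if not np.isfinite(values).all():
        raise ConfigurationError("reference region contains non-finite intensities")

    q75, q25 = np.percentile(values, (75, 25))
    iqr = q75 - q25
    span = float(values.max() - values.min())
    if span == 0.0:
        return float(values[0])
    width = 2.0 * iqr / values.size ** (1.0 / 3.0)
    if width <= 0:  # heavy ties: fall back to Sturges-like binning of the span
        width = span / max(1, int(np.ceil(np.log2(values.size) + 1)))
    n_bins = max(1, int(np.ceil(span / width)))
    counts, edges = np.histogram(values, bins=n_bins)
    k = int(np.argmax(counts))
    center = 0.5 * (edges[k] + edges[k + 1])
    if 0 < k < n_bins - 1:
        ym, y0, yp = counts[k - 1], counts[k], counts[k + 1]
        denom = ym - 2 * y0 + yp
        if denom != 0:
            center += 0.5 * (ym - yp) / denom * (edges[1] - edges[0])
    return float(center)


def calibrate(
    image: np.ndarray,
    eye_mask: np.ndarray,
    muscle_mask: np.ndarray,
    target_low: float = DEFAULT_TARGET_LOW,
    target_high: float = DEFAULT_TARGET_HIGH,
) -> tuple[np.ndarray, CalibrationResult]:
    """Affine-map ``image`` so its eye and muscle modal intensities hit the targets."""
    ref_low = find_reference_peak(image, eye_mask)
    ref_high = find_reference_peak(image, muscle_mask)
    if ref_high == ref_low:
        raise DegenerateCalibrationError(
            f"eye and muscle reference peaks coincide at {ref_low}; cannot calibrate"
        )
    slope = (target_high - target_low) / (ref_high - ref_low)
    intercept = target_low - slope * ref_low
    calibrated = slope * np.asarray(image, dtype=float) + intercept
    return calibrated, CalibrationResult(
        slope=slope,
        intercept=intercept,
        ref_low_peak=ref_low,
        ref_high_peak=ref_high,
        target_low=target_low,
        target_high=target_high,
    )


def compute_ratio_map(
    t1w_cal: np.ndarray,
    t2w_cal: np.ndarray,
    epsilon: float | None = None,
    target_high: float = DEFAULT_TARGET_HIGH,
) -> np.ndarray:
    """Voxel-wise t1w_cal / t2w_cal; voxels with denominator ≤ epsilon become NaN.

    Epsilon defaults to ``DEFAULT_EPSILON_FRACTION * target_high`` — it only
    guards against true zeros in the calibrated T2w image. Invalid voxels are
    marked NaN for downstream exclusion, never clipped.
    """
    t1w_cal = np.asarray(t1w_cal, dtype=float)
    t2w_cal = np.asarray(t2w_cal, dtype=float)
    if t1w_cal.shape != t2w_cal.shape:
        raise GridMismatchError(f"shape mismatch {t1w_cal.shape} vs {t2w_cal.shape}")
    if epsilon is None:
        epsilon = DEFAULT_EPSILON_FRACTION * abs(target_high)
    valid = t2w_cal > epsilon
    out = np.full(t1w_cal.shape, np.nan, dtype=float)
    np.divide(t1w_cal, t2w_cal, out=out, where=valid)
    return out


def reconstruct_rt1t2(
    t1w: np.ndarray,
    t2w: np.ndarray,
    eye_mask: np.ndarray | None,
    muscle_mask: np.ndarray | None,
    target_low: float = DEFAULT_TARGET_LOW,
    target_high: float = DEFAULT_TARGET_HIGH,
    epsilon: float | None = None,
) -> np.ndarray:
    """Full rT1/T2 reconstruction: calibrate both images, then divide.

    When the reference masks are absent the weighted images are taken as
    already calibrated and only the division is performed.
    """
    if eye_mask is not None and muscle_mask is not None:
        t1w, _ = calibrate(t1w, eye_mask, muscle_mask, target_low, target_high)
        t2w, _ = calibrate(t2w, eye_mask, muscle_mask, target_low, target_high)
    return compute_ratio_map(t1w, t2w, epsilon=epsilon, target_high=target_high)
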