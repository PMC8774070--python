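"""The LMPH statistic: class-conditional histogram contrast of rT1/T2.

For a histogram bin k with nH(k) of NH Met-PET-high voxels and nL(k) of NL
Met-PET-low voxels, the Likeliness of Met-PET high is

    LMPH(k) = (nH(k)/NH - nL(k)/NL) / (nH(k)/NH + nL(k)/NL),

a normalized contrast of class proportions in [-1, 1]: +1 in bins occupied
only by high voxels, -1 in bins occupied only by low voxels, 0 where the
proportions balance, and undefined where both counts are zero — voxels that
fall in undefined bins are removed from the analysis rather than scored.
The learned per-bin values form a conversion table that turns any rT1/T2
map into a voxel-wise LMPH map.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DegenerateTrainingError, InconsistencyError

log = logging.getLogger(__name__)

#: default rT1/T2 histogram support — the range the ratio mainly occupies in tumor VOIs
DEFAULT_RANGE = (0.3, 1.3)
#: default uniform bin width (50 bins over the default range)
DEFAULT_BIN_WIDTH = 0.02


@dataclass(frozen=True)
class HistogramSpec:
    """Uniform binning of the rT1/T2 axis.

    Bins are half-open ``[edge_i, edge_{i+1})`` with the final bin closed at
    ``hi``; values outside ``[lo, hi]`` are excluded, never clamped.
    """

    lo: float = DEFAULT_RANGE[0]
    hi: float = DEFAULT_RANGE[1]
    bin_width: float = DEFAULT_BIN_WIDTH

    def __post_init__(self) -> None:
        if not (self.hi > self.lo):
            raise ConfigurationError(f"histogram range [{self.lo}, {self.hi}] is empty")
        if self.bin_width <= 0:
            raise ConfigurationError(f"bin width must be positive, got {self.bin_width}")
        n = (self.hi - self.lo) / self.bin_width
        if abs(n - round(n)) > 1e-9 * max(1.0, n):
            raise ConfigurationError(
                f"bin width {self.bin_width} does not evenly tile [{self.lo}, {self.hi}]"
            )

    @property
    def n_bins(self) -> int:
        return int(round((self.hi - self.lo) / self.bin_width))

    @property
    def bin_edges(self) -> np.ndarray:
        return self.lo + self.bin_width * np.arange(self.n_bins + 1)

    def assign_bins(self, values: np.ndarray) -> np.ndarray:
        """Bin index per value; -1 for values outside [lo, hi]."""
        values = np.asarray(values, dtype=float)
        idx = np.digitize(values, self.bin_edges, right=False) - 1
        # values at (or float-epsilon beyond) the top edge belong to the closed last bin
        idx = np.minimum(idx, self.n_bins - 1)
        idx[(values < self.lo) | (values > self.hi) | ~np.isfinite(values)] = -1
        return idx


@dataclass
class LMPHConversion:
    """Learned bin → LMPH lookup with its class-conditional histograms.

    ``lmph`` is NaN in undefined bins (both class counts zero); undefined
    bins are stored explicitly and never imputed.
    """

    spec: HistogramSpec
    nH: np.ndarray
    nL: np.ndarray
    NH: int
    NL: int
    lmph: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.nH = np.asarray(self.nH, dtype=np.int64)
        self.nL = np.asarray(self.nL, dtype=np.int64)
        if self.nH.sum() != self.NH or self.nL.sum() != self.NL:
            raise InconsistencyError(
                f"per-bin counts (sums {self.nH.sum()}, {self.nL.sum()}) "
                f"disagree with totals (NH={self.NH}, NL={self.NL})"
            )
        self.lmph = compute_lmph_array(self.nH, self.nL, self.NH, self.NL)

    @property
    def defined(self) -> np.ndarray:
        return (self.nH + self.nL) > 0

    def to_frame(self) -> pd.DataFrame:
        edges = self.spec.bin_edges
        return pd.DataFrame(
            {
                "bin_lo": edges[:-1],
                "bin_hi": edges[1:],
                "nH": self.nH,
                "nL": self.nL,
                "lmph": self.lmph,
            }
        )

    def save(self, csv_path: str | Path) -> None:
        """Write the conversion table as CSV plus a JSON sidecar with totals and binning."""
        csv_path = Path(csv_path)
        frame = self.to_frame()
        frame.to_csv(csv_path, index=False, float_format="%.10g", na_rep="")
        header = {
            "NH": int(self.NH),
            "NL": int(self.NL),
            "spec": {"lo": self.spec.lo, "hi": self.spec.hi, "bin_width": self.spec.bin_width},
        }
        csv_path.with_suffix(".json").write_text(json.dumps(header, indent=2) + "\n")

    @classmethod
    def load(cls, csv_path: str | Path) -> "LMPHConversion":
        csv_path = Path(csv_path)
        frame = pd.read_csv(csv_path)
        header = json.loads(csv_path.with_suffix(".json").read_text())
        spec = HistogramSpec(**header["spec"])
        return cls(
            spec=spec,
            nH=frame["nH"].to_numpy(),
            nL=frame["nL"].to_numpy(),
            NH=int(header["NH"]),
            NL=int(header["NL"]),
        )


def build_histograms(
    table: pd.DataFrame, spec: HistogramSpec
) -> tuple[np.ndarray, np.ndarray, int, int]:
    """Class-conditional per-bin counts (nH, nL) and totals (NH, NL) from a voxel table.

    Voxels outside the histogram support are excluded from both the per-bin
    counts and the totals, with the excluded count logged.
    """
    if len(table) == 0:
        raise ConfigurationError("cannot build histograms from an empty voxel table")
    values = table["rt1t2"].to_numpy(dtype=float)
    high = (table["met_class"].to_numpy() == "high")
    bins = spec.assign_bins(values)
    outside = bins < 0
    if outside.any():
        log.info("excluded %d voxels outside histogram range [%g, %g]",
                 int(outside.sum()), spec.lo, spec.hi)
    nH = np.bincount(bins[high & ~outside], minlength=spec.n_bins).astype(np.int64)
    nL = np.bincount(bins[~high & ~outside], minlength=spec.n_bins).astype(np.int64)
    return nH, nL, int(nH.sum()), int(nL.sum())


def compute_lmph(nH_k: int, nL_k: int, NH: int, NL: int) -> float:
    """LMPH of a single bin; NaN when the bin is empty in both classes."""
    if nH_k > 0 and NH == 0:
        raise InconsistencyError(f"nH(k)={nH_k} with NH=0")
    if nL_k > 0 and NL == 0:
        raise InconsistencyError(f"nL(k)={nL_k} with NL=0")
    if nH_k == 0 and nL_k == 0:
        return math.nan
    pH = nH_k / NH if NH > 0 else 0.0
    pL = nL_k / NL if NL > 0 else 0.0
    return (pH - pL) / (pH + pL)


def compute_lmph_array(nH: np.ndarray, nL: np.ndarray, NH: int, NL: int) -> np.ndarray:
    """Vectorized LMPH over all bins; NaN where both class counts are zero."""
    nH = np.asarray(nH, dtype=float)
    nL = np.asarray(nL, dtype=float)
    if (nH > 0).any() and NH == 0:
        raise InconsistencyError("positive nH(k) with NH=0")
    if (nL > 0).any() and NL == 0:
        raise InconsistencyError("positive nL(k) with NL=0")
    pH = nH / NH if NH > 0 else np.zeros_like(nH)
    pL = nL / NL if NL > 0 else np.zeros_like(nL)
    out = np.full(nH.shape, np.nan)
    occupied = (nH + nL) > 0
    np.divide(pH - pL, pH + pL, out=out, where=occupied)
    return out


def build_conversion(table: pd.DataFrame, spec: HistogramSpec | None = None) -> LMPHConversion:
    """Learn the bin → LMPH conversion table from a labelled voxel table.

    Requires both Met-PET classes to be represented (NH > 0 and NL > 0);
    a single-class table makes the contrast degenerate and the caller must
    decide how to handle the patient (typically exclusion).
    """
    spec = spec or HistogramSpec()
    nH, nL, NH, NL = build_histograms(table, spec)
    if NH == 0 or NL == 0:
        raise DegenerateTrainingError(
            f"training table must contain both classes within the histogram range "
            f"(NH={NH}, NL={NL})"
        )
    return LMPHConversion(spec=spec, nH=nH, nL=nL, NH=NH, NL=NL)


def apply_conversion(
    ratio_map: np.ndarray,
    voi_mask: np.ndarray,
    conv: LMPHConversion,
) -> np.ndarray:
    """Convert an rT1/T2 map into an LMPH map over the VOI.

    VOI voxels falling outside the histogram support or into undefined bins
    are NaN in the output (excluded from downstream scoring); everything
    outside the VOI is NaN as well. Exclusion counts are logged.
    """
    ratio_map = np.asarray(ratio_map, dtype=float)
    voi_mask = np.asarray(voi_mask)
    if ratio_map.shape != voi_mask.shape:
        raise ConfigurationError(
            f"ratio map shape {ratio_map.shape} != VOI mask shape {voi_mask.shape}"
        )
    out = np.full(ratio_map.shape, np.nan)
    inside = voi_mask > 0
    bins = conv.spec.assign_bins(ratio_map[inside])
    scores = np.full(bins.shape, np.nan)
    in_range = bins >= 0
    scores[in_range] = conv.lmph[bins[in_range]]
    n_out_of_range = int((~in_range).sum())
    n_undefined = int(np.isnan(scores[in_range]).sum())
    if n_out_of_range or n_undefined:
        log.info("LMPH map: excluded %d out-of-range and %d undefined-bin VOI voxels",
                 n_out_of_range, n_undefined)
    out[inside] = scores
    return out
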