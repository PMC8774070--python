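"""Exponential link between rT1/T2 and tissue relaxation times.

Voxel-wise rT1/T2 decays roughly exponentially with both T1- and
T2-relaxation time, r = a * exp(b * t) with b < 0 — the empirical basis for
treating the ratio map as a relaxometry surrogate. The model is fitted in
log space: ordinary least squares of ln(r) on t, with a = exp(intercept)
and b = slope. The reported Pearson r and two-sided p refer to the
linearized relation (t, ln r), the only scale on which a single correlation
coefficient is well-defined for this model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import DomainError, SampleSizeError


@dataclass(frozen=True)
class ExpFit:
    """Fitted exponential r = a * exp(b * t) with its linearized correlation."""

    a: float        # amplitude (unitless ratio at t = 0)
    b: float        # rate per ms; negative for a decaying link
    r: float        # Pearson correlation of (t, ln ratio)
    p: float        # two-sided p-value of the correlation
    n: int          # voxels used


def fit_exponential(ratio_values: np.ndarray, relax_times: np.ndarray) -> ExpFit:
    """Fit r = a * exp(b * t) by least squares on ln(r).

    ``ratio_values`` must be strictly positive (the log link is undefined
    otherwise); at least 3 paired observations are required.
    """
    ratio_values = np.asarray(ratio_values, dtype=float).ravel()
    relax_times = np.asarray(relax_times, dtype=float).ravel()
    if ratio_values.shape != relax_times.shape:
        raise DomainError(
            f"length mismatch: {ratio_values.size} ratios vs {relax_times.size} relaxation times"
        )
    bad = int((~np.isfinite(ratio_values) | (ratio_values <= 0)).sum())
    if bad:
        raise DomainError(f"{bad} ratio values are non-positive or non-finite; log link undefined")
    if ratio_values.size < 3:
        raise SampleSizeError(f"need at least 3 observations, got {ratio_values.size}")
    res = stats.linregress(relax_times, np.log(ratio_values))
    return ExpFit(
        a=float(np.exp(res.intercept)),
        b=float(res.slope),
        r=float(res.rvalue),
        p=float(res.pvalue),
        n=int(ratio_values.size),
    )
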