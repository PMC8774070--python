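"""Exception hierarchy for the lmphmap pipeline."""


class LmphmapError(Exception):
    """Base class for all pipeline errors."""


class ConfigurationError(LmphmapError, ValueError):
    """Invalid or missing configuration (missing manifest role, empty mask, bad parameters)."""


class GridMismatchError(LmphmapError, ValueError):
    """Volumes do not share a compatible voxel grid / shape."""


class DegenerateCalibrationError(LmphmapError, ValueError):
    """The two reference peaks coincide; the affine intensity map is undefined."""


class NormalReferenceError(LmphmapError, ValueError):
    """The normal-tissue PET reference is empty or has non-positive mean activity."""


class DomainError(LmphmapError, ValueError):
    """Input values outside the mathematical domain of an operation (e.g. non-positive ratios)."""


class SampleSizeError(LmphmapError, ValueError):
    """Too few observations for the requested fit or test."""


class InconsistencyError(LmphmapError, ValueError):
    """Histogram counts contradict their stated totals."""


class DegenerateTrainingError(LmphmapError, ValueError):
    """A training table contains only one Met-PET class; the conversion is undefined."""


class ClassCoverageError(LmphmapError, ValueError):
    """ROC requested on a single-class label set."""


class DegenerateTestError(LmphmapError, ValueError):
    """A statistical test on a zero-variance sample."""


class EmptyCVError(LmphmapError, ValueError):
    """Every patient was excluded from cross-validation."""
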