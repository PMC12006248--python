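"""Exception hierarchy shared across the package."""


class AblaquantError(Exception):
    """Base class for all package errors."""


class InvalidGeometryError(AblaquantError):
    """Electrode or domain geometry violates its invariants."""


class SolverError(AblaquantError):
    """Field solver failed to converge within the iteration budget."""

    def __init__(self, message: str, residual: float | None = None):
        super().__init__(message)
        self.residual = residual


class InvalidRegionError(AblaquantError):
    """Requested region is empty, unknown, or outside the solved domain."""


class OutOfRangeError(AblaquantError):
    """A measured quantity lies outside the range the model can invert."""


class InconsistentWaveformError(AblaquantError):
    """Burst energized time is not an integer number of bipolar cycles."""


class DegenerateStainsError(AblaquantError):
    """Stain matrix is singular or nearly so; deconvolution is ill-posed."""


class DegenerateHistogramError(AblaquantError):
    """Image histogram has fewer than two occupied bins; no threshold exists."""


class InvalidROIError(AblaquantError):
    """Region of interest is empty, self-intersecting, or outside the image."""


class TrainingError(AblaquantError):
    """Classifier training inputs are degenerate (e.g. a single class)."""


class FeatureError(AblaquantError):
    """Required object features are missing or not populated."""


class ParameterError(AblaquantError):
    """A configuration parameter is outside its valid range."""


class InvalidAnnotationError(AblaquantError):
    """Node/artifact annotations are inconsistent (artifacts >= node area)."""


class InsufficientStandardsError(AblaquantError):
    """Too few standard points to fit a calibration curve."""


class GatedFitError(AblaquantError):
    """Standard curve failed its goodness-of-fit gate and may not be used."""


class NormalizationError(AblaquantError):
    """Missing or invalid reference for normalization."""


class FitError(AblaquantError):
    """Nonlinear curve fit failed to converge."""


class InvalidBaselineError(AblaquantError):
    """Baseline volume for percent change is non-positive."""


class InvalidFractionError(AblaquantError):
    """Ablation fraction outside [0, 1)."""


class TransformError(AblaquantError):
    """Data cannot be transformed as configured (e.g. log of non-positive)."""


class UndefinedCorrelationError(AblaquantError):
    """Correlation undefined because one input has zero variance."""
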