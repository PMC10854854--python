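"""Exception hierarchy for the CT-perfusion pipeline.

Curve-fit failures are first-class outcomes (a non-enhancing ROI is a
clinical reality, not a bug), so they get typed exceptions that the cohort
pipeline can catch, log and report per patient.
"""


class CTPerfError(Exception):
    """Base class for all package errors."""


class CurveValidationError(CTPerfError, ValueError):
    """A time-intensity curve violates its invariants."""


class InsufficientSamplesError(CurveValidationError):
    """Too few samples for the requested operation."""


class InsufficientPhaseSupportError(CTPerfError, ValueError):
    """The upslope window leaves fewer than two samples in the
    non-enhancement or washout phase ("insufficient phase support")."""


class DegenerateGeometryError(CTPerfError, ValueError):
    """Fitted upslope and washout lines do not intersect with the peak
    after the onset ("degenerate geometry")."""


class NonEnhancingCurveError(CTPerfError, ValueError):
    """Fitted upslope slope is not positive ("non-enhancing curve")."""


class SegmentationError(CTPerfError, ValueError):
    """Label map and dynamic series are inconsistent, or an ROI is empty."""


class StageError(CTPerfError, RuntimeError):
    """Wraps a component error with the pipeline stage where it occurred."""

    def __init__(self, stage: str, original: Exception):
        self.stage = stage
        self.original = original
        super().__init__(f"[{stage}] {original}")
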