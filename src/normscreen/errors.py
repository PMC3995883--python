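"""Exception hierarchy shared across the package."""


class NormscreenError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(NormscreenError):
    """A record or argument violates a documented invariant."""


class FormatError(NormscreenError):
    """A file is structurally malformed (missing column, bad header)."""


class RowParseError(FormatError):
    """A CSV row could not be parsed; carries the 1-based data row number."""

    def __init__(self, row: int, message: str):
        self.row = row
        super().__init__(f"row {row}: {message}")


class ClassificationError(NormscreenError):
    """A record is missing a field required by the diagnostic rules."""


class FeasibilityError(NormscreenError):
    """Requested target moments cannot be realised by the distribution family."""


class DegenerateNormError(NormscreenError):
    """A norming model has zero residual spread and cannot standardise scores."""


class SingularFitError(NormscreenError):
    """Design matrix is rank-deficient (constant or collinear predictors)."""


class UndefinedValueError(NormscreenError):
    """A ratio or correlation is undefined for the given input (e.g. ISR = 0)."""


class RocError(NormscreenError):
    """ROC analysis is impossible (an empty class, etc.)."""


class PipelineError(NormscreenError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
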