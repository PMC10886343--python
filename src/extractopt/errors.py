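"""Exception hierarchy shared across the pipeline stages."""


class ExtractOptError(Exception):
    """Base class for all package-specific errors."""


class DesignError(ExtractOptError):
    """Unsupported or malformed experimental design."""


class SingularDesignError(ExtractOptError):
    """The model matrix is rank-deficient and cannot be fit by OLS."""


class AnovaError(ExtractOptError):
    """ANOVA decomposition impossible (e.g. no replicate runs for pure error)."""


class SplitError(ExtractOptError):
    """A train/validation/test partition came out empty."""


class DivergenceError(ExtractOptError):
    """Network training produced a non-finite loss."""

    def __init__(self, message, history=None):
        super().__init__(message)
        self.history = history


class FormulaError(ExtractOptError):
    """Elemental formula cannot be parsed or lacks a removable hydrogen."""


class AnnotationError(ExtractOptError):
    """Invalid annotation request (e.g. empty compound library)."""


class AssayError(ExtractOptError):
    """Invalid assay arithmetic input (non-positive control absorbance etc.)."""


class NotEstimableError(ExtractOptError):
    """IC50 cannot be interpolated because inhibition never crosses 50%."""

    def __init__(self, message, bound=None):
        super().__init__(message)
        #: "> max" or "< min" — which side of the tested range the IC50 lies on.
        self.bound = bound


class ValidationError(ExtractOptError):
    """Optimum validation arithmetic received a non-positive prediction."""


class PipelineIOError(ExtractOptError):
    """Stage-tagged I/O failure (malformed CSV, missing column, bad config)."""

    def __init__(self, stage, message):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage
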