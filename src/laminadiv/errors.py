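"""Exception hierarchy for laminadiv.

All pipeline-raised errors derive from :class:`LaminadivError` so callers can
catch the package's failures without also catching programming errors.
"""


class LaminadivError(Exception):
    """Base class for all laminadiv errors."""


class FormatError(LaminadivError):
    """An input file does not conform to its expected dialect (bad header,
    wrong field count, non-numeric value).  Carries a line number when one
    is known."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


class ValidationError(LaminadivError):
    """Well-formed input violating a domain invariant (p-value outside (0, 1],
    duplicate gene identifier, confidence outside [0, 1], cyclic term graph)."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


class ParameterError(LaminadivError, ValueError):
    """A function argument outside its documented range (alpha, bin width,
    top_k, inconsistent hypergeometric counts)."""


class InsufficientDataError(LaminadivError):
    """Too little data to compute the requested statistic (e.g. fewer than
    three shared genes for a correlation, empty contribution table)."""


class ConfigurationError(LaminadivError):
    """Invalid run or synthetic-data configuration (fractions not summing to
    one, missing cohort, missing input path)."""


class PipelineError(LaminadivError):
    """A stage of the orchestrated pipeline failed; names the stage and wraps
    the original error."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause
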