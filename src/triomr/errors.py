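"""Exception hierarchy shared across the pipeline stages."""


class TrioMRError(Exception):
    """Base class for all triomr errors."""


class ParameterError(TrioMRError, ValueError):
    """A configuration or function parameter is outside its valid range."""


class InputError(TrioMRError, ValueError):
    """An input record or dataset violates a precondition."""


class ValidationError(TrioMRError, ValueError):
    """A loaded table failed schema or consistency validation."""


class RankDeficiencyError(TrioMRError):
    """A regression design matrix is rank deficient.

    Carries the names of the collinear columns so the caller can see
    which covariates to drop or recode.
    """

    def __init__(self, columns):
        self.columns = list(columns)
        super().__init__(
            "design matrix is rank deficient; collinear columns: "
            + ", ".join(self.columns)
        )


class PipelineStageError(TrioMRError):
    """A pipeline stage failed; wraps the underlying error with a stage code."""

    def __init__(self, stage: str, code: str, cause: Exception):
        self.stage = stage
        self.code = code
        self.cause = cause
        super().__init__(f"stage '{stage}' failed [{code}]: {cause}")
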