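"""Exception types shared across the pipeline."""


class SealdiveError(Exception):
    """Base class for all package errors."""


class FormatError(SealdiveError):
    """An input file violates its format contract (missing column, bad enum...)."""


class DataError(SealdiveError):
    """Structurally valid input that violates a semantic contract."""


class FitError(SealdiveError):
    """A model fit failed to converge; carries diagnostic state."""

    def __init__(self, message, last_objective=None):
        super().__init__(message)
        self.last_objective = last_objective
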