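"""Exception hierarchy shared across the pipeline."""


class CardioMRError(Exception):
    """Base class for all cardiomr errors."""


class DomainError(CardioMRError, ValueError):
    """An argument is outside the mathematical domain of an operation."""


class ConfigError(CardioMRError, ValueError):
    """A configuration object violates its invariants."""


class MissingColumnError(CardioMRError, KeyError):
    """A required summary-statistics column is absent from the input file."""

    def __init__(self, field: str, column: str):
        self.field = field
        self.column = column
        super().__init__(f"required field {field!r} (column {column!r}) not found in header")

    def __str__(self) -> str:  # KeyError quotes its arg; keep the message readable
        return self.args[0]


class EmptyFileError(CardioMRError, ValueError):
    """The summary-statistics file has a header but no data rows."""


class MalformedFileError(CardioMRError, ValueError):
    """Every data row of a summary-statistics file failed validation."""


class InsufficientInstrumentsError(CardioMRError, ValueError):
    """Fewer instruments than the estimator's minimum."""


class DegenerateDesignError(CardioMRError, ValueError):
    """The regression design is singular (e.g. all exposure effects equal)."""


class UnknownVariantError(CardioMRError, KeyError):
    """Strict LD mode encountered a variant absent from the reference."""
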