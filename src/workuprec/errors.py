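"""Exception hierarchy shared across the package."""


class WorkupRecError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(WorkupRecError, ValueError):
    """An input table is missing a required column or has an invalid layout."""


class RowParseError(WorkupRecError, ValueError):
    """A single row of an input table could not be parsed.

    Carries the 1-based file line number (header = line 1) in ``line``.
    """

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class InvalidRangeError(WorkupRecError, ValueError):
    """A lab reference range has ref_low > ref_high."""


class UndefinedQueryError(WorkupRecError, KeyError):
    """A conditional statistic was requested for a query item with N_A = 0."""


class ColdStartError(WorkupRecError, LookupError):
    """No query item is present in the trained vocabulary; caller must fall back."""


class ConfigurationError(WorkupRecError, ValueError):
    """Inconsistent run configuration (bad split year, too few episodes, ...)."""


class UntrainedModelError(WorkupRecError, RuntimeError):
    """A recommendation was requested from an empty/untrained association matrix."""


class UndefinedMetricError(WorkupRecError, ValueError):
    """A metric is undefined on the given input (e.g. empty actual set, one class)."""
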