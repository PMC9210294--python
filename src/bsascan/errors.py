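"""Exception types shared across the package."""


class BsaScanError(Exception):
    """Base class for all package errors."""


class ConfigurationError(BsaScanError):
    """A user-supplied configuration value or input layout is invalid."""


class ParseError(BsaScanError):
    """A record in an input file could not be parsed.

    Carries the 1-based line number of the offending row when known.
    """

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


class ContractViolation(BsaScanError):
    """An operation was applied to data violating its precondition."""


class EstimationError(BsaScanError):
    """A quantity could not be estimated from the available data."""
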