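"""Exception hierarchy shared by all stages of the pipeline."""


class CeftripkError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(CeftripkError):
    """A domain-type invariant was violated."""


class SchemaError(CeftripkError):
    """An input table is missing a required column."""


class ParseError(CeftripkError):
    """A cell could not be parsed; message carries the row index."""


class ConfigError(CeftripkError):
    """A generator or pipeline configuration is infeasible."""


class DomainError(CeftripkError):
    """A numeric argument is outside the mathematical domain of an operation."""


class InsufficientDataError(CeftripkError):
    """Too few observations for the requested estimation."""


class ConvergenceError(CeftripkError):
    """The optimizer failed on every start; best-found attached as .best."""

    def __init__(self, message, best=None):
        super().__init__(message)
        self.best = best


class PairingError(CeftripkError):
    """Total/free samples could not be matched at a common time."""
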