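"""Exception hierarchy shared across the package."""


class UnibrainnetError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(UnibrainnetError, ValueError):
    """Invalid user input: bad model parameters, malformed matrices, etc."""


class MatrixParseError(ValidationError):
    """A delimited-text matrix file could not be parsed."""


class SolverDivergenceError(UnibrainnetError, RuntimeError):
    """A numerical iteration produced non-finite values or failed to converge."""
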