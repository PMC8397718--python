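"""Exception hierarchy shared across the package."""


class ZipfBiasError(Exception):
    """Base class for all package-specific errors."""


class DivergenceError(ZipfBiasError, ValueError):
    """The normalizer diverges (unbounded event set with exponent <= 1)."""


class DomainError(ZipfBiasError, ValueError):
    """A parameter or argument is outside its mathematical domain."""


class BoundaryError(ZipfBiasError, RuntimeError):
    """A maximum-likelihood search terminated on the boundary of the
    search interval, so no interior estimate exists for this data."""


class PermanentSizeError(ZipfBiasError, ValueError):
    """The permutation-sum likelihood was requested for an event set too
    large for exact permanent computation (O(W 2^W) cost)."""


class InconsistencyError(ZipfBiasError, RuntimeError):
    """Two independent numerical routes (maximization vs gradient root)
    disagree beyond tolerance."""


class ParseError(ZipfBiasError, ValueError):
    """A data file could not be parsed; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class SimulationCapError(ZipfBiasError, RuntimeError):
    """An ABC generation exhausted its simulation budget before accepting
    the requested number of particles."""


class DegenerateError(ZipfBiasError, RuntimeError):
    """A particle population or regression design is degenerate (zero
    variance), so the requested quantity is undefined."""
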