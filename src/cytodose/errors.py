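"""Exception hierarchy for cytodose."""


class CytodoseError(Exception):
    """Base class for all cytodose errors."""


class UndefinedStatisticError(CytodoseError):
    """A statistic is mathematically undefined for the given data
    (e.g. the u-test with zero total aberrations)."""


class PoolingError(CytodoseError):
    """Distributions cannot be pooled (mixed doses or assays)."""


class ConvergenceError(CytodoseError):
    """Iterative fit failed to converge; carries the last iterate."""

    def __init__(self, message, last_coefficients=None):
        super().__init__(message)
        self.last_coefficients = last_coefficients


class DomainError(CytodoseError):
    """Input outside the mathematical domain of an operation
    (e.g. inverting a curve below its background yield)."""


class SchemaError(CytodoseError):
    """Malformed input file or configuration."""


class PipelineError(CytodoseError):
    """A pipeline stage failed; message names the stage."""
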