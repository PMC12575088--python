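"""Exception hierarchy shared across the package.

All errors raised on bad user input derive from :class:`ProteoallocError`
so callers (and the CLI) can catch one base class; subclasses also derive
from the closest builtin (``ValueError``) for idiomatic handling.
"""


class ProteoallocError(Exception):
    """Base class for all errors raised by proteoalloc."""


class FormatError(ProteoallocError, ValueError):
    """An input file does not conform to the expected tabular dialect."""


class ValidationError(ProteoallocError, ValueError):
    """Parsed content violates an invariant (duplicates, empty sets, ...)."""


class DegenerateSampleError(ProteoallocError, ValueError):
    """A sample carries no positive intensity; mass fractions are undefined."""


class FitError(ProteoallocError, ValueError):
    """A regression cannot be performed on the points provided."""


class CalibrationError(ProteoallocError, ValueError):
    """A standard curve is degenerate (too few or collinear standards)."""


class EstimationError(ProteoallocError, ValueError):
    """An estimator could not locate the feature it needs (e.g. no
    steady exponential window in a downshift curve)."""


class DomainError(ProteoallocError, ValueError):
    """A numeric argument is outside the physically meaningful domain."""


class ConfigError(ProteoallocError, ValueError):
    """A run or generator configuration is inconsistent."""
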