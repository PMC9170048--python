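"""Exception hierarchy shared across the package.

Anticipated failure modes get their own class so callers (and the CLI) can
turn them into one-line diagnostics instead of stack traces.
"""


class BehavdimError(Exception):
    """Base class for all anticipated errors."""


class ParameterError(BehavdimError, ValueError):
    """A model or simulation parameter is out of its valid range."""


class SizeError(BehavdimError, ValueError):
    """A requested size (samples, lags, window) is invalid or too small."""


class StabilityError(BehavdimError, ValueError):
    """A drift matrix has a non-decaying mode; the process is not stationary."""


class ConditioningError(BehavdimError, ArithmeticError):
    """A covariance/kernel matrix is too ill-conditioned to invert reliably."""


class CoverageError(BehavdimError, ValueError):
    """An estimated correlation does not cover the lags a window requires."""


class ModelError(BehavdimError, ValueError):
    """A model specification is internally inconsistent (e.g. non-PSD)."""


class CapacityError(BehavdimError, ValueError):
    """An exact discrete-state computation exceeds the supported state count."""


class FitError(BehavdimError, RuntimeError):
    """An iterative fit failed to reach the requested tolerance."""
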