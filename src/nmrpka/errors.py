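"""Exception hierarchy.

All exceptions derive from :class:`NmrPkaError` so callers can catch the
package's failures with a single except clause; subclasses distinguish
domain violations, solver non-convergence, and data/fit pathologies.
"""


class NmrPkaError(Exception):
    """Base class for all nmrpka errors."""


class DomainError(NmrPkaError, ValueError):
    """An input is outside the physically meaningful domain."""


class ConvergenceError(NmrPkaError, RuntimeError):
    """An iterative solver failed to converge; the message carries the bracket."""


class DataError(NmrPkaError, ValueError):
    """A measurement table violates the schema or contains unusable values."""


class InsufficientDataError(DataError):
    """Fewer usable points than the operation requires."""


class UnphysicalFitError(NmrPkaError, RuntimeError):
    """A fit converged to a state with no physical interpretation (e.g. C <= 0)."""


class NoTitrationError(NmrPkaError, RuntimeError):
    """The data show no dependence of kappa on pH; no acid is being titrated."""


class CalibrationError(NmrPkaError, RuntimeError):
    """Limiting-shift calibration is impossible on the supplied dataset."""


class ConfigError(NmrPkaError, ValueError):
    """A configuration file is missing required keys or names unknown entities."""
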