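"""Exception types raised across the package."""


class CarepathError(Exception):
    """Base class for package errors."""


class ArgumentError(CarepathError, ValueError):
    """Invalid argument or configuration value."""


class EmptyCohortError(ArgumentError):
    """An operation requiring a non-empty cohort received an empty one."""


class SafetyViolationError(CarepathError, RuntimeError):
    """A policy emitted an action forbidden by its action mask."""


class FitError(CarepathError, RuntimeError):
    """Model fitting failed (e.g. degenerate single-class outcome labels)."""


class NotFittedError(CarepathError, RuntimeError):
    """A model was used before being fitted."""


class UndefinedRateError(CarepathError, ValueError):
    """A group rate (TPR/FPR) is undefined for a named group."""


class ChecksumMismatchError(CarepathError, RuntimeError):
    """A checkpoint's state-feature dictionary hash does not match this build."""
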