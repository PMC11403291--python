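"""Exception hierarchy shared by all analysis engines."""


class ProfilerError(Exception):
    """Base class for all package errors."""


class InputError(ProfilerError, ValueError):
    """Raised when an input value or table violates a precondition."""


class FitError(ProfilerError, RuntimeError):
    """Raised when a curve fit fails to converge or is ill-posed."""


class NoDoseDependenceError(FitError):
    """Raised when the response range is too flat to support a dose-response fit."""


class NotQuantifiableError(ProfilerError):
    """Raised when no valid calibration model exists for a metabolite."""
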