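"""Exception types shared across the fitting modules."""


class StarbrushError(Exception):
    """Base class for package errors."""


class FitError(StarbrushError, RuntimeError):
    """A fit failed to converge or produced unusable parameters."""

    def __init__(self, message: str, trace: list | None = None):
        super().__init__(message)
        self.trace = trace or []


class InsufficientDataError(FitError):
    """Too few usable points for the requested analysis."""


class UnsupportedGeometryError(StarbrushError, ValueError):
    """An operation was requested for a core geometry it is not defined on."""
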