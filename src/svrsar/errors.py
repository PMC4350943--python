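"""Exception hierarchy shared across the package."""


class SvrSarError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(SvrSarError):
    """A domain object violates one of its invariants."""


class ParseError(SvrSarError):
    """A dataset file could not be parsed.

    Carries the 1-based line number of the offending line when known.
    """

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


class UndefinedScoreError(SvrSarError):
    """Raw discontinuity is undefined: no compound pair qualifies (Tc >= t).

    Callers decide policy; the score is never silently reported as zero."""


class DegeneratePanelError(SvrSarError):
    """Reference-panel raw scores have zero spread; Z-normalization impossible."""


class ConvergenceError(SvrSarError):
    """The SVR optimizer (or MDS embedding) failed to converge."""

    def __init__(self, message: str, C: float | None = None):
        if C is not None:
            message = f"{message} (C={C})"
        super().__init__(message)
        self.C = C


class ConfigError(SvrSarError):
    """A study configuration is malformed, incomplete, or out of range."""
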