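"""Exception hierarchy for the drydown package."""


class DrydownError(Exception):
    """Base class for all package errors."""


class ConfigError(DrydownError, ValueError):
    """Invalid configuration or parameter values."""


class TimelineError(DrydownError, ValueError):
    """Water-potential timeline cannot be built or evaluated."""


class AnalysisError(DrydownError, ValueError):
    """Analysis precondition violated (empty input, degenerate series, ...)."""


class FitError(DrydownError, RuntimeError):
    """Curve fitting failed to converge; carries optimizer diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class GenerationError(DrydownError, ValueError):
    """Synthetic data generation failed (e.g. conduit outside the frame)."""
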