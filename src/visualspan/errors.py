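"""Exception types raised across the pipeline."""


class VisualSpanError(Exception):
    """Base class for all package-specific errors."""


class InvalidTrialError(VisualSpanError):
    """A trial is inconsistent with the governing session design."""


class IncompleteProfileError(VisualSpanError):
    """A scored position has no observations for some participant x complexity."""


class FitSelectionError(VisualSpanError):
    """Neither candidate curve fit converged; no span can be reported."""


class IncompleteDesignError(VisualSpanError):
    """A span table is missing participant x complexity cells."""


class DegenerateDesignError(VisualSpanError):
    """Too few participants per group for inference."""


class UndefinedCorrelationError(VisualSpanError):
    """Correlation requested on degenerate input (n < 3 or zero variance)."""


class InvalidRecordError(VisualSpanError):
    """A reading record violates basic constraints (e.g. non-positive time)."""


class ConfigError(VisualSpanError):
    """A generator or pipeline configuration field is invalid."""
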