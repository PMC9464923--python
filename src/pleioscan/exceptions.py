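"""Exception hierarchy for pleioscan."""


class PleioscanError(Exception):
    """Base class for all pleioscan errors."""


class ConfigurationError(PleioscanError):
    """Invalid configuration: missing mandatory columns, bad parameter values."""


class EmptyInputError(PleioscanError):
    """An operation received (or produced) zero usable records."""


class DegenerateInputError(PleioscanError):
    """Input is formally valid but statistically degenerate (e.g. all-zero z)."""


class FitError(PleioscanError):
    """Model fitting failed to converge from every start."""

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class AlignmentError(PleioscanError):
    """Two inputs that must share a SNP set do not."""
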