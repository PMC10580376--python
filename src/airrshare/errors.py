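"""Exception hierarchy.

Everything raised on purpose derives from :class:`AirrShareError`, so callers
(and the CLI) can separate anticipated failures from genuine bugs.
"""


class AirrShareError(Exception):
    """Base class for all errors raised deliberately by this package."""


class ConfigurationError(AirrShareError):
    """A configuration value or model definition is invalid."""


class ValidationError(AirrShareError):
    """An input value violates a documented precondition."""


class SchemaError(AirrShareError):
    """A file does not conform to the expected tabular schema."""


class UnknownGeneError(AirrShareError, KeyError):
    """A V or J gene identifier is not present in the generative model."""


class ResourceError(AirrShareError):
    """An operation would exceed a hard resource guard (e.g. enumeration size)."""


class ModelUnusableError(AirrShareError):
    """An incidence model has no usable rows for the requested query."""


class EngineUnavailableError(AirrShareError, ImportError):
    """An external V(D)J recombination engine is not installed."""


class FeasibilityError(AirrShareError):
    """Signal implantation was requested for an infeasible configuration.

    Carries the :class:`~airrshare.simulate.FeasibilityReport` so the caller
    can inspect the shortfall diagnostics.
    """

    def __init__(self, message, report):
        super().__init__(message)
        self.report = report
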