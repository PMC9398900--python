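"""Exception hierarchy for proteonoise.

All errors derive from :class:`ProteoNoiseError` so callers can catch the
package's failures with a single except clause.  Most also derive from the
closest builtin (``ValueError``/``RuntimeError``) so generic handling keeps
working.
"""


class ProteoNoiseError(Exception):
    """Base class for all proteonoise errors."""


class ConfigurationError(ProteoNoiseError, ValueError):
    """An invalid simulation or analysis configuration."""


class ValidationError(ProteoNoiseError, ValueError):
    """Invalid input values (out-of-range probabilities, bad shapes, ...)."""


class DegenerateArrayError(ProteoNoiseError, ValueError):
    """A sample whose control spots make normalization uninterpretable."""


class SchemaError(ProteoNoiseError, ValueError):
    """Inconsistent analyte lists or unmatched subjects across inputs."""


class InsufficientDataError(ProteoNoiseError, ValueError):
    """Too few samples/values for the requested statistic."""


class ModeUnavailableError(ProteoNoiseError, ValueError):
    """The requested noise-score mode cannot be computed from this matrix."""


class DegenerateFitError(ProteoNoiseError, ValueError):
    """A clock fit on degenerate input (e.g. all ages identical)."""


class PredictionDisabledError(ProteoNoiseError, RuntimeError):
    """Prediction from a clock whose slope is exactly zero."""
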