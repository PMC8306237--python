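"""Exception hierarchy for the ivimhsi pipeline.

Every stage raises a subclass of :class:`IvimHsiError` so that the pipeline
driver can attach the stage name and fail cleanly.
"""


class IvimHsiError(Exception):
    """Base class for all ivimhsi errors."""


class InvalidSpecError(IvimHsiError, ValueError):
    """A phantom or run specification is internally inconsistent."""


class ConfigurationError(IvimHsiError, ValueError):
    """Missing or contradictory configuration (e.g. unknown tissue class)."""


class FormatError(IvimHsiError, ValueError):
    """An on-disk input does not match the expected layout."""


class NoForegroundError(IvimHsiError, ValueError):
    """An image contains no usable foreground (all zero / empty mask)."""


class EmptyDetectionError(IvimHsiError, RuntimeError):
    """A detector produced (or was handed) an empty lesion mask."""


class DegenerateInputError(IvimHsiError, ValueError):
    """Input is degenerate for the requested operation (e.g. constant map)."""


class UndefinedMetricError(IvimHsiError, ValueError):
    """A similarity metric is undefined for the given masks."""
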