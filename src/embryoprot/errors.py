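"""Exception hierarchy shared across the pipeline.

Exit-code mapping used by the command-line layer: config errors -> 2,
data-format errors -> 3, computation errors -> 4.
"""


class EmbryoprotError(Exception):
    """Base class for all package errors."""


class ConfigError(EmbryoprotError):
    """Invalid or incomplete pipeline configuration."""


class FormatError(EmbryoprotError):
    """A file violates its declared external format."""


class InvalidParameterError(EmbryoprotError, ValueError):
    """An operation was called with out-of-contract parameters."""


class InvalidInputError(EmbryoprotError, ValueError):
    """An in-memory input violates the operation's preconditions."""


class InsufficientDataError(EmbryoprotError):
    """Not enough usable data to perform the requested computation."""


class DegenerateFitError(EmbryoprotError):
    """A model fit is undefined for the given data (e.g. zero slope)."""
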