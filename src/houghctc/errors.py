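"""Exception hierarchy for the CTC counting pipeline."""


class HoughCTCError(Exception):
    """Base class for all pipeline errors."""


class DimensionError(HoughCTCError):
    """Image planes or masks do not share the same height x width."""


class FormatError(HoughCTCError):
    """An input file has an unsupported layout (e.g. wrong plane count)."""


class ConfigurationError(HoughCTCError):
    """A required configuration value is missing or out of range."""


class DegenerateHistogramError(HoughCTCError):
    """A plane is constant, so no automatic threshold can be computed."""


class CapacityError(HoughCTCError):
    """The synthetic scene cannot pack the requested number of objects."""


class InsufficientDataError(HoughCTCError):
    """Too few observations for the requested statistic."""
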