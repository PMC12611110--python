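"""Exception hierarchy for the disparity package."""


class DisparityError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(DisparityError, ValueError):
    """Invalid configuration value or unknown key."""


class SchemaError(DisparityError, ValueError):
    """Input file violates the declared schema (missing columns/properties)."""


class ValidationError(DisparityError, ValueError):
    """Data fails a consistency check (negative counts, duplicates, ...)."""


class DegenerateVarianceError(DisparityError, ValueError):
    """A statistic is undefined because the input has zero variance."""


class InsufficientDataError(DisparityError, ValueError):
    """Too few observations for the requested statistic."""
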