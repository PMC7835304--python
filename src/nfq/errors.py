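"""Exception types shared across the pipeline."""


class NFQError(Exception):
    """Base class for pipeline errors."""


class SizingError(NFQError, ValueError):
    """Requested grid cannot hold the phantom anatomy."""


class ConfigurationError(NFQError, ValueError):
    """Invalid or incomplete run/generator configuration."""


class DegenerateGeometryError(NFQError, ValueError):
    """Landmark configuration too degenerate for the requested fit."""


class DegenerateDataError(NFQError, ValueError):
    """Input data degenerate for the requested estimate (empty region,
    zero-variance histogram, non-positive intensities, ...)."""
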