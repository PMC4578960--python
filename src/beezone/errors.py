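"""Exception hierarchy shared across the package."""


class ZoningError(Exception):
    """Base class for all beezone errors."""


class ConfigurationError(ZoningError, ValueError):
    """A run configuration (weights, quota, algorithm parameters) is invalid."""


class InstanceError(ZoningError, ValueError):
    """A problem instance or solution violates its contract (shape, range, quota)."""


class RasterIOError(ZoningError, IOError):
    """A raster file could not be read or written, or layers disagree."""
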