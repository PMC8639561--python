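"""Exception hierarchy shared across the package."""


class StructuratorError(Exception):
    """Base class for all package errors."""


class InputError(StructuratorError, ValueError):
    """Invalid argument or precondition violation."""


class DimensionError(InputError):
    """Frames or grids with inconsistent shapes."""


class CapacityError(InputError):
    """Memory budget too small to hold even one wave vector's workspace."""


class FitError(InputError):
    """Fit preconditions not met (too few lags or rings)."""
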