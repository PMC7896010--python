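"""Exception types shared across the package."""


class RenshawError(Exception):
    """Base class for package errors."""


class ConfigurationError(RenshawError, ValueError):
    """A configuration object violates one of its invariants."""


class InsufficientDataError(RenshawError, ValueError):
    """Not enough data (triggers, segments, significant bins, curves)."""


class GridError(RenshawError, ValueError):
    """Frequency or lag grids of combined objects do not match."""


class SupportError(RenshawError, ValueError):
    """A required time shift exceeds the support of an averaged response."""


class StabilityError(RenshawError, RuntimeError):
    """Numerical integration diverged; retry with a smaller time step."""


class UndefinedMeanError(RenshawError, ValueError):
    """Circular mean undefined: resultant vector length is (near) zero."""
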