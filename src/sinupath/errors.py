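"""Exception hierarchy shared across the package."""


class SinupathError(Exception):
    """Base class for all package-specific errors."""


class InvalidTrajectoryError(SinupathError):
    """Trajectory violates a structural invariant (too few vertices, bad times)."""


class DegenerateTrajectoryError(SinupathError):
    """Trajectory is structurally valid but carries no usable signal
    (e.g. all steps have zero length)."""


class TimeOrderError(InvalidTrajectoryError):
    """Timestamps are not strictly increasing."""


class TooCoarseError(SinupathError):
    """Requested rediscretization step exceeds the total path length."""


class InsufficientReplicationError(SinupathError):
    """A statistical group has too few observations."""


class DegenerateVarianceError(SinupathError):
    """Within-group variance is zero; F statistic undefined."""


class AliasedTermError(SinupathError):
    """Design matrix is rank deficient; names the offending terms."""


class ConfigError(SinupathError):
    """Invalid simulation or pipeline configuration."""


class SchemaError(SinupathError):
    """Input file is missing required columns or malformed."""
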