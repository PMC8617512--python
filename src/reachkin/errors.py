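"""Exception hierarchy shared across the package."""


class ReachKinError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(ReachKinError):
    """Invalid configuration value or parameter combination."""


class FormatError(ReachKinError):
    """Malformed trial file or unmappable marker labels."""


class ManifestError(ReachKinError):
    """Invalid cohort manifest (duplicate keys, inconsistent groups...)."""


class ShapeError(ReachKinError):
    """Array arguments with inconsistent or insufficient dimensions."""


class MissingDependencyError(ReachKinError):
    """An optional third-party dependency is required but not installed."""


class NoMovementError(ReachKinError):
    """A velocity series with no positive peak cannot be segmented."""


class DegenerateInputError(ReachKinError):
    """Geometrically or statistically degenerate input (collinear markers,
    zero-length segment vectors, constant reference curve, ...)."""


class UnrecoverableMarkerError(ReachKinError):
    """A marker has too few valid samples to reconstruct its trajectory."""
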