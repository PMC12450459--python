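"""Exception hierarchy.

Data errors (bad inputs, malformed files, degenerate geometry) map to CLI
exit code 1; configuration errors to exit code 2.
"""


class DesmomapError(Exception):
    """Base class for all package errors."""


class ConfigError(DesmomapError):
    """Invalid or incomplete run configuration."""


class DataError(DesmomapError):
    """Invalid data passed to an operation."""


class GeometryError(DataError):
    """Degenerate or infeasible geometry (non-positive separation, arcsine out of range, ...)."""


class FormatError(DataError):
    """A file does not conform to the expected format (e.g. missing column)."""


class ParseError(FormatError):
    """A cell could not be parsed; carries the offending row number."""


class ProfileError(DataError):
    """A cross-junction profile is unusable (constant, too short, empty)."""


class OrientationError(DataError):
    """Junction orientation cannot be determined (near-isotropic intensity)."""
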