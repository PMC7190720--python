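"""Exception hierarchy.

Pipeline exit codes map ConfigError -> 2 and DataError subclasses -> 3.
"""


class GrapekinError(Exception):
    """Base class for all package errors."""


class ConfigError(GrapekinError):
    """Invalid configuration (bad YAML, unknown keys, missing files)."""


class DataError(GrapekinError):
    """Invalid or unusable input data."""


class DataFormatError(DataError):
    """A file does not follow the declared dialect."""


class IncomparableProfilesError(DataError):
    """Two profiles share zero non-missing loci."""


class TooFewLociError(DataError):
    """Not enough shared informative loci for a pairwise estimate."""


class CalibrationError(DataError):
    """No reference relationships available and no manual thresholds given."""
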