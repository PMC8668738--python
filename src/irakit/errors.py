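"""Exception hierarchy shared across the package.

The CLI maps these onto exit codes: configuration errors -> 2,
data/alignment errors -> 3, numerical failures -> 4.
"""


class IrakitError(Exception):
    """Base class for all package errors."""


class ConfigError(IrakitError):
    """Invalid configuration (bad parameter ranges, missing paths)."""


class DataError(IrakitError):
    """Invalid data (domain violations: gaps, zero variance, bad shapes)."""


class AlignmentError(DataError):
    """Two inputs that must share a year axis do not."""


class NumericalError(IrakitError):
    """A fit or decomposition failed numerically."""
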