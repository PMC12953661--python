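"""Exception hierarchy shared across the package.

Exit-code mapping used by the CLI:
  ConfigurationError -> 2, DataError -> 3, ConvergenceError -> 4.
"""


class LesionnetError(Exception):
    """Base class for all package errors."""


class ConfigurationError(LesionnetError):
    """Invalid configuration: bad counts, unknown metric names, bad ranges."""


class DataError(LesionnetError):
    """Invalid or inconsistent input data: shape mismatches, bad values."""


class ConvergenceError(LesionnetError):
    """An iterative fit failed to converge or was degenerate."""
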