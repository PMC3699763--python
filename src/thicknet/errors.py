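"""Exception hierarchy.

``ThicknetError`` is the base; ``DataError`` marks malformed or inconsistent
input (bad tables, rank-deficient designs, out-of-range parameters) and maps
to exit code 2 in the command-line interface.
"""


class ThicknetError(ValueError):
    """Base class for all package-specific errors."""


class DataError(ThicknetError):
    """Malformed, missing or inconsistent input data."""


class SpecError(ThicknetError):
    """Invalid simulation or run configuration."""
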