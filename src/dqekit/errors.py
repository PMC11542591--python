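"""Exception hierarchy shared across the package.

``DataError`` marks invalid or degenerate inputs (bad images, mismatched
grids); ``NumericalError`` marks failures of the estimation itself (fits that
cannot be formed, non-positive spectra).  The CLI maps them to distinct exit
codes.
"""


class DqekitError(Exception):
    """Base class for all package-specific errors."""


class DataError(DqekitError):
    """Input data are invalid, degenerate, or inconsistent."""


class NumericalError(DqekitError):
    """A numerical estimation step failed."""
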