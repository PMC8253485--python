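"""Exception hierarchy shared across the package."""


class AquaError(Exception):
    """Base class for all errors raised by aquanmr."""


class ParseError(AquaError):
    """A spectrum or table file could not be parsed (message names the line)."""


class GridError(AquaError):
    """The ppm axis of a spectrum file is not a uniform arithmetic progression."""


class RangeError(AquaError):
    """A ppm position or window falls outside the spectral axis."""


class ConfigError(AquaError):
    """Invalid configuration (noise region too small, inconsistent simulation setup, ...)."""


class LibraryError(AquaError):
    """Invalid compound library entry (zero reporter height, missing response factor, ...)."""


class MatrixError(AquaError):
    """The interference matrix is singular or too ill-conditioned to solve."""


class PeakShapeError(AquaError):
    """A peak's half-height crossings could not be located on either side."""
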