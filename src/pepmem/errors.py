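"""Exception hierarchy used across pepmem.

All pepmem errors derive from :class:`PepmemError`; most also subclass the
closest builtin (ValueError) so callers who do not care about fine-grained
handling can still catch them idiomatically.
"""


class PepmemError(Exception):
    """Base class for all pepmem errors."""


class SpectrumParseError(PepmemError, ValueError):
    """A tabular input file could not be parsed; the message names the row."""


class InsufficientDataError(PepmemError, ValueError):
    """Too few points for the requested fit or estimate."""


class OutOfRangeError(PepmemError, ValueError):
    """A query falls outside the supported/invertible range of the data."""


class WavelengthRangeError(OutOfRangeError):
    """Requested wavelength lies outside the spectrum's grid."""


class DegenerateInputError(PepmemError, ValueError):
    """Input is degenerate for the operation (e.g. zero denominator scale)."""


class ExtrapolationError(PepmemError, ValueError):
    """A double-reciprocal extrapolation produced a non-physical result."""


class FitError(PepmemError, RuntimeError):
    """A model fit failed or returned a non-physical parameter."""


class GeneratorError(PepmemError, ValueError):
    """Requested synthetic-data parameters are infeasible for the generator."""
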