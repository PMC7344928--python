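"""Exception hierarchy for diffdenoise.

All library errors derive from :class:`DiffDenoiseError` so callers can
catch the package's failures with a single except clause; each concrete
class also derives from the matching builtin (ValueError / RuntimeError)
so existing generic handlers keep working.
"""


class DiffDenoiseError(Exception):
    """Base class for all diffdenoise errors."""


class ShapeError(DiffDenoiseError, ValueError):
    """Image/field shapes are incompatible or below the stencil minimum."""


class InvalidInputError(DiffDenoiseError, ValueError):
    """Input contains non-finite values or violates a domain precondition."""


class ParameterError(DiffDenoiseError, ValueError):
    """A configuration parameter is outside its admissible range."""


class FormatError(DiffDenoiseError, ValueError):
    """Unsupported raster format, dtype, or channel layout."""


class NumericalDivergenceError(DiffDenoiseError, RuntimeError):
    """The explicit scheme produced non-finite values (blow-up).

    Attributes
    ----------
    step : int
        Index of the iteration at which non-finite values first appeared.
    """

    def __init__(self, message: str, step: int):
        super().__init__(message)
        self.step = step
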