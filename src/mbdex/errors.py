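"""Exception hierarchy shared across analysis stages."""


class MbdexError(Exception):
    """Base class for all package errors."""


class InvalidInputError(MbdexError, ValueError):
    """A parameter or data value violates a precondition."""


class UnderDeterminedError(MbdexError, ValueError):
    """Fewer observations than free parameters."""


class FitFailureError(MbdexError, RuntimeError):
    """Optimizer failed to converge or produced a degenerate solution."""


class DegenerateGeometryError(MbdexError, ValueError):
    """Geometry (bond vectors, atom sets) has insufficient rank."""


class ParseError(MbdexError, ValueError):
    """A data file is malformed; message names the offending line."""
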