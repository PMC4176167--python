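"""Random-coil dimensions of an unstructured polypeptide linker.

For a freely jointed chain with limiting characteristic ratio C_inf, n
residues and mean link (Calpha-Calpha) length l, the root-mean-square
end-to-end distance is sqrt(C_inf * n * l^2).  Dividing by the helical
rise of B-form DNA converts that reach into a number of base pairs the
chain can span — the basis for arguing that a ~280-residue disordered
linker lets two DNA-binding domains of one protein occupy sites ~50+ bp
apart on the same molecule.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import InvalidInputError

__all__ = ["ChainModel", "end_to_end_length", "bp_span"]

#: limiting characteristic ratio for a disordered polypeptide
DEFAULT_C_INF = 9.27
#: average Calpha-Calpha distance, Angstrom
DEFAULT_LINK_A = 3.8
#: B-DNA helical rise, Angstrom per base pair
DEFAULT_RISE_A = 3.4


@dataclass(frozen=True)
class ChainModel:
    """Freely jointed chain parameters (lengths in Angstrom)."""

    n: int
    c_inf: float = DEFAULT_C_INF
    l: float = DEFAULT_LINK_A
    rise: float = DEFAULT_RISE_A

    def __post_init__(self) -> None:
        if self.n < 0:
            raise InvalidInputError("residue count must be >= 0")
        if self.c_inf <= 0 or self.l <= 0 or self.rise <= 0:
            raise InvalidInputError("c_inf, l and rise must be > 0")


def end_to_end_length(chain: ChainModel) -> float:
    """RMS end-to-end distance sqrt(c_inf * n * l^2) in Angstrom."""
    return math.sqrt(chain.c_inf * chain.n * chain.l**2)


def bp_span(length: float, rise: float = DEFAULT_RISE_A, floor: bool = False) -> float:
    """Base pairs of B-DNA spanned by a contour length (fractional by default)."""
    if length < 0 or rise <= 0:
        raise InvalidInputError("length must be >= 0 and rise > 0")
    span = length / rise
    return float(math.floor(span)) if floor else span
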