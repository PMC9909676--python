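"""Element universe and pinned isotope data.

The package models molecules over the eight-element universe
``(H, C, O, N, F, S, P, Cl)`` — the elements that give near-complete
coverage of small organic molecules in the large EI-MS libraries.  The
universe order is fixed and every count vector in the package is aligned
to it.

Isotope exact masses (Da) and natural abundances are pinned here as
literals rather than read from a chemistry toolkit at run time, so the
observation model is bit-stable across toolkit versions.  Values are the
standard IUPAC/CODATA ones at natural terrestrial abundance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

#: Fixed universe order.  Index into this tuple is the canonical element index
#: used by every count vector, encoding, and feature block in the package.
ELEMENTS: Tuple[str, ...] = ("H", "C", "O", "N", "F", "S", "P", "Cl")

ELEMENT_INDEX: Dict[str, int] = {e: i for i, e in enumerate(ELEMENTS)}

#: Per-element isotope table: (exact mass in Da, natural abundance fraction).
#: Abundances for each element sum to 1 within 1e-9.
ISOTOPES: Dict[str, Tuple[Tuple[float, float], ...]] = {
    "H": ((1.00782503207, 0.999885), (2.01410177785, 0.000115)),
    "C": ((12.0, 0.9893), (13.00335483780, 0.0107)),
    "O": (
        (15.99491461956, 0.99757),
        (16.99913170, 0.00038),
        (17.99916107, 0.00205),
    ),
    "N": ((14.00307400480, 0.99636), (15.00010889820, 0.00364)),
    "F": ((18.99840322, 1.0),),
    "S": (
        (31.97207100, 0.9499),
        (32.97145876, 0.0075),
        (33.96786690, 0.0425),
        (35.96708076, 0.0001),
    ),
    "P": ((30.97376163, 1.0),),
    "Cl": ((34.96885268, 0.7576), (36.96590259, 0.2424)),
}

#: Standard valences used by the synthetic molecule generator.
VALENCE: Dict[str, int] = {"H": 1, "C": 4, "O": 2, "N": 3, "F": 1, "S": 2, "P": 3, "Cl": 1}


class UnsupportedElementError(ValueError):
    """An element outside the (H, C, O, N, F, S, P, Cl) universe was seen."""

    def __init__(self, symbol: str):
        self.symbol = symbol
        super().__init__(
            f"element {symbol!r} is outside the supported universe {ELEMENTS}"
        )


@dataclass(frozen=True)
class ElementUniverse:
    """The fixed 8-element universe with its isotope table.

    A single module-level instance :data:`UNIVERSE` is what the rest of the
    package uses; the class exists so the invariants are checkable and the
    table is carried around as one object.
    """

    elements: Tuple[str, ...] = ELEMENTS
    isotopes: "Dict[str, Tuple[Tuple[float, float], ...]]" = None  # type: ignore[assignment]

    def __post_init__(self):
        if self.isotopes is None:
            object.__setattr__(self, "isotopes", ISOTOPES)
        for e in self.elements:
            total = sum(a for _, a in self.isotopes[e])
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"abundances for {e} sum to {total}, not 1")

    def index(self, symbol: str) -> int:
        try:
            return ELEMENT_INDEX[symbol]
        except KeyError:
            raise UnsupportedElementError(symbol) from None

    def monoisotopic_mass(self, symbol: str) -> float:
        """Mass of the most abundant isotope of ``symbol``."""
        return max(self.isotopes[symbol], key=lambda p: p[1])[0]

    def mean_mass(self, symbol: str) -> float:
        """Abundance-weighted mean isotope mass (standard atomic weight)."""
        return sum(m * a for m, a in self.isotopes[symbol])


UNIVERSE = ElementUniverse()


def element_indices(symbols: Sequence[str]) -> List[int]:
    """Map element symbols to universe indices, erroring on foreign elements."""
    return [UNIVERSE.index(s) for s in symbols]
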