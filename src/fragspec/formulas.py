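"""Chemical formulas and exhaustive subformula enumeration.

A fragment's formula is a length-8 count vector aligned to the universe
order (H, C, O, N, F, S, P, Cl).  Enumerating every subformula of a
molecular formula is the setwise Cartesian product of the per-element
ranges ``0..count_e``, so a formula with counts ``(c_1, ..., c_8)`` has
exactly ``prod(c_e + 1)`` subformulae — C6H12O6 has 7 x 13 x 7 = 637.
Enumeration is structure-blind by design: no valence or connectivity
constraint is applied.

Two model-facing encodings are provided: the plain count matrix and the
run-length ("N-hot") bit encoding in which each element occupies a block
of ``maxelem`` bits whose first ``count`` bits are set.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .elements import ELEMENTS, ELEMENT_INDEX, UNIVERSE

#: Default cap on enumeration size before raising.
DEFAULT_ENUMERATION_CAP = 2**20

#: Default run-length block capacity: the training filters cap molecules at
#: 48 atoms, so no single element count can exceed 48.
DEFAULT_MAXELEM = 48


class EnumerationOverflowError(RuntimeError):
    """Subformula enumeration would exceed the configured cap."""


class EncodingCapacityError(ValueError):
    """An element count exceeds the run-length block capacity ``maxelem``."""


@dataclass(frozen=True, order=True)
class Formula:
    """An element-count vector over the 8-element universe.

    Hashable and totally ordered (lexicographic over universe-ordered
    counts) so formulas can live in sets and sorted lists.
    """

    counts: Tuple[int, ...]

    def __post_init__(self):
        if len(self.counts) != len(ELEMENTS):
            raise ValueError(f"need {len(ELEMENTS)} counts, got {len(self.counts)}")
        if any(c < 0 for c in self.counts):
            raise ValueError(f"negative count in {self.counts}")

    @classmethod
    def from_dict(cls, counts: dict) -> "Formula":
        vec = [0] * len(ELEMENTS)
        for sym, n in counts.items():
            vec[UNIVERSE.index(sym)] = int(n)
        return cls(tuple(vec))

    @classmethod
    def from_string(cls, text: str) -> "Formula":
        """Parse a Hill-ish formula string like ``"C6H12O6"`` or ``"CH3"``."""
        import re

        counts = [0] * len(ELEMENTS)
        pos = 0
        for m in re.finditer(r"([A-Z][a-z]?)(\d*)", text):
            if m.start() != pos or not m.group(1):
                break
            pos = m.end()
            sym, num = m.group(1), m.group(2)
            counts[UNIVERSE.index(sym)] += int(num) if num else 1
        if pos != len(text.strip()):
            raise ValueError(f"cannot parse formula string {text!r}")
        return cls(tuple(counts))

    @property
    def total_atoms(self) -> int:
        return sum(self.counts)

    def count(self, symbol: str) -> int:
        return self.counts[ELEMENT_INDEX[symbol]]

    def is_empty(self) -> bool:
        return self.total_atoms == 0

    def dominates(self, other: "Formula") -> bool:
        """True if every count of ``other`` is <= the matching count here."""
        return all(o <= s for s, o in zip(self.counts, other.counts))

    def __str__(self) -> str:
        return hill_string(self) or "(empty)"


def hill_string(formula: Formula) -> str:
    """Hill-order string: C first, then H, then other elements alphabetically."""
    parts = []
    order = ["C", "H"] + sorted(e for e in ELEMENTS if e not in ("C", "H"))
    for sym in order:
        n = formula.count(sym)
        if n == 1:
            parts.append(sym)
        elif n > 1:
            parts.append(f"{sym}{n}")
    return "".join(parts)


def subformula_count(formula: Formula) -> int:
    """Number of subformulae of ``formula``: prod over elements of (count+1)."""
    n = 1
    for c in formula.counts:
        n *= c + 1
    return n


@dataclass
class FormulaSet:
    """Ordered, duplicate-free collection of subformulae of one molecular formula."""

    formulas: List[Formula]
    parent: Optional[Formula] = None

    def __len__(self) -> int:
        return len(self.formulas)

    def __iter__(self):
        return iter(self.formulas)

    def __getitem__(self, i):
        return self.formulas[i]

    def index_of(self, f: Formula) -> int:
        return self.formulas.index(f)


def enumerate_subformulae(
    formula: Formula, cap: int = DEFAULT_ENUMERATION_CAP
) -> FormulaSet:
    """Enumerate every formula dominated by ``formula``.

    The recursion getSub(X_N ++ rest) = [X_0..X_N] (x) getSub(rest) is
    realised as an iterated Cartesian product over the per-element ranges.
    The result includes the empty formula and ``formula`` itself, has
    exactly ``prod(count_e + 1)`` members, and is ordered lexicographically
    over universe-ordered counts.
    """
    n = subformula_count(formula)
    if n > cap:
        raise EnumerationOverflowError(
            f"{formula} has {n} subformulae, exceeding the cap of {cap}"
        )
    ranges = [range(c + 1) for c in formula.counts]
    members = [Formula(t) for t in itertools.product(*ranges)]
    return FormulaSet(members, parent=formula)


def count_encode(fs: FormulaSet) -> np.ndarray:
    """Stack a FormulaSet into an (n_formulas, 8) integer count matrix."""
    if len(fs) == 0:
        raise ValueError("empty FormulaSet")
    return np.array([f.counts for f in fs], dtype=np.int64)


def count_decode(matrix: np.ndarray) -> FormulaSet:
    """Inverse of :func:`count_encode`."""
    return FormulaSet([Formula(tuple(int(x) for x in row)) for row in matrix])


@dataclass(frozen=True)
class RunLengthEncoding:
    """Per-element blocks of ``maxelem`` bits; the first ``count`` bits are set.

    By default all 8 universe blocks are emitted in universe order.  A
    restricted display (e.g. the two-element (H, C) display used in worked
    examples) can be requested explicitly via ``display``.
    """

    bits: Tuple[int, ...]
    maxelem: int
    display: Tuple[str, ...] = ELEMENTS

    def as_array(self) -> np.ndarray:
        return np.array(self.bits, dtype=np.float64)


def run_length_encode(
    formula: Formula,
    maxelem: int = DEFAULT_MAXELEM,
    display: Sequence[str] = ELEMENTS,
) -> RunLengthEncoding:
    """Run-length one-hot encode ``formula``.

    ``display`` selects which element blocks appear (full universe by
    default); e.g. CH3 with ``maxelem=5`` over display ``("H", "C")`` gives
    ``[1,1,1,0,0, 1,0,0,0,0]``.
    """
    bits: List[int] = []
    for sym in display:
        c = formula.count(sym)
        if c > maxelem:
            raise EncodingCapacityError(
                f"count {c} for element {sym} exceeds maxelem={maxelem}"
            )
        bits.extend([1] * c + [0] * (maxelem - c))
    return RunLengthEncoding(tuple(bits), maxelem, tuple(display))


def run_length_encode_batch(
    formulas: Iterable[Formula],
    maxelem: int = DEFAULT_MAXELEM,
    display: Sequence[str] = ELEMENTS,
) -> np.ndarray:
    """Encode many formulas into an (n, len(display) * maxelem) 0/1 matrix."""
    rows = [run_length_encode(f, maxelem, display).bits for f in formulas]
    return np.array(rows, dtype=np.float64)
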