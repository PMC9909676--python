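"""Exact isotopic peak distributions for formulas at natural abundance.

The mass distribution of a fragment with a given formula is the
distribution of the sum of per-atom isotope masses, with each atom's
isotope drawn independently at natural abundance.  It is computed by
iterated convolution of the per-element single-atom distributions,
merging peaks whose masses agree to within 1e-9 Da.  Probabilities below
``prune_below`` are dropped at the end and deliberately NOT renormalized,
so conservation checks downstream can detect over-pruning.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np

from .elements import ELEMENTS, ISOTOPES
from .formulas import Formula

MERGE_TOL = 1e-9


@dataclass(frozen=True)
class IsotopePeakDistribution:
    """(mass, probability) peaks for one formula; masses strictly increasing."""

    masses: np.ndarray
    probabilities: np.ndarray
    formula: Optional[Formula] = None

    def __len__(self) -> int:
        return len(self.masses)

    @property
    def peaks(self) -> List[Tuple[float, float]]:
        return list(zip(self.masses.tolist(), self.probabilities.tolist()))

    def total_probability(self) -> float:
        return float(self.probabilities.sum())

    def mean_mass(self) -> float:
        return float(np.dot(self.masses, self.probabilities) / self.probabilities.sum())


def _merge(masses: np.ndarray, probs: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Sort by mass and sum probabilities of peaks within MERGE_TOL."""
    order = np.argsort(masses, kind="stable")
    masses, probs = masses[order], probs[order]
    if len(masses) == 0:
        return masses, probs
    group = np.zeros(len(masses), dtype=np.int64)
    gid = 0
    anchor = masses[0]
    for i in range(1, len(masses)):
        if masses[i] - anchor > MERGE_TOL:
            gid += 1
            anchor = masses[i]
        group[i] = gid
    n_groups = gid + 1
    out_m = np.zeros(n_groups)
    out_p = np.zeros(n_groups)
    np.add.at(out_p, group, probs)
    # weighted mean mass within a group keeps merged masses stable
    np.add.at(out_m, group, masses * probs)
    out_m /= np.maximum(out_p, 1e-300)
    return out_m, out_p


def _convolve(
    m1: np.ndarray, p1: np.ndarray, m2: np.ndarray, p2: np.ndarray
) -> Tuple[np.ndarray, np.ndarray]:
    masses = (m1[:, None] + m2[None, :]).ravel()
    probs = (p1[:, None] * p2[None, :]).ravel()
    return _merge(masses, probs)


def _element_power(symbol: str, n: int) -> Tuple[np.ndarray, np.ndarray]:
    """Distribution of the summed mass of ``n`` atoms of one element,
    via binary exponentiation of the single-atom distribution."""
    iso = ISOTOPES[symbol]
    base_m = np.array([m for m, _ in iso])
    base_p = np.array([a for _, a in iso])
    res_m, res_p = np.array([0.0]), np.array([1.0])
    while n:
        if n & 1:
            res_m, res_p = _convolve(res_m, res_p, base_m, base_p)
        n >>= 1
        if n:
            base_m, base_p = _convolve(base_m, base_p, base_m, base_p)
    return res_m, res_p


def isotope_distribution(
    formula: Formula, prune_below: float = 1e-6
) -> IsotopePeakDistribution:
    """Exact isotopic peak distribution of ``formula`` at natural abundance.

    With ``prune_below=0`` the probabilities sum to exactly 1 (up to
    float rounding); with pruning, low-probability peaks are removed
    without renormalization.  The empty formula yields an empty peak list.
    """
    if formula.is_empty():
        return IsotopePeakDistribution(np.array([]), np.array([]), formula)
    masses, probs = np.array([0.0]), np.array([1.0])
    for sym, count in zip(ELEMENTS, formula.counts):
        if count:
            em, ep = _element_power(sym, count)
            masses, probs = _convolve(masses, probs, em, ep)
    if prune_below > 0:
        keep = probs >= prune_below
        masses, probs = masses[keep], probs[keep]
    return IsotopePeakDistribution(masses, probs, formula)


def monoisotopic_mass(formula: Formula) -> float:
    """Sum of most-abundant-isotope masses."""
    total = 0.0
    for sym, count in zip(ELEMENTS, formula.counts):
        if count:
            total += count * max(ISOTOPES[sym], key=lambda p: p[1])[0]
    return total
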