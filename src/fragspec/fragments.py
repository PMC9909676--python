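"""Atom-subset enumeration by recursive bond breaking plus hydrogen rearrangement.

Fragments are represented as *atom subsets* (vertex subsets of the parent
molecule), not bond-resolved subgraphs: the mass peaks of a fragment
depend only on which atoms it contains, and the subset space is vastly
smaller than the subgraph space.  Plausible subsets are generated by
recursively breaking all possible bonds out to a depth ``d`` (default 3)
and collecting the connected components, then optionally applying
hydrogen rearrangements — moving up to ``max_h_transfer`` hydrogens into
and/or out of each subset — which mass spectrometrists observe routinely
in EI fragmentation.

Subsets are stored as integer bitmasks over the parent molecule's atom
indices (bit ``i`` = atom ``i`` present), which makes deduplication and
set algebra cheap.

Bond removals are enumerated as unordered combinations of at most ``d``
bonds (removing bonds {a, b} once, not in both orders): the components
of a simultaneous removal do not depend on the order of the breaks, so
this avoids the factorial blow-up of ordered break sequences without
losing any subset.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np

from .chem import Molecule
from .elements import ELEMENTS, UNIVERSE
from .formulas import Formula


class SubsetOverflowError(RuntimeError):
    """Enumeration produced more subsets than the configured hard ceiling."""


@dataclass(frozen=True)
class FragmentationConfig:
    """Settings for subset generation.

    depth: number of bond breaks ``d`` (0 = only the intact molecule).
    hydrogen_rearrangement: apply +-H transfers after bond breaking.
    max_h_transfer: hydrogens that may move in or out of a subset (each).
    max_subsets: random cap applied after dedup (None = uncapped).
    heavy_bonds_only: restrict breakable bonds to heavy-heavy bonds.
    keep_single_hydrogens: retain lone-H subsets (default yes).
    hard_ceiling: abort if the pre-cap enumeration exceeds this.
    """

    depth: int = 3
    hydrogen_rearrangement: bool = True
    max_h_transfer: int = 2
    max_subsets: Optional[int] = 12288
    seed: int = 0
    heavy_bonds_only: bool = False
    keep_single_hydrogens: bool = True
    hard_ceiling: int = 2**22

    def __post_init__(self):
        if self.depth < 0:
            raise ValueError("depth must be >= 0")
        if self.max_h_transfer < 0:
            raise ValueError("max_h_transfer must be >= 0")
        if self.max_subsets is not None and self.max_subsets <= 0:
            raise ValueError("max_subsets must be positive")


@dataclass(frozen=True, order=True)
class AtomSubset:
    """A non-empty subset of one molecule's atoms, as a bitmask."""

    mask: int
    n_atoms: int  # of the parent molecule

    def __post_init__(self):
        if self.mask <= 0:
            raise ValueError("subset must be non-empty")
        if self.mask >> self.n_atoms:
            raise ValueError("mask exceeds parent atom range")

    def indices(self) -> List[int]:
        return [i for i in range(self.n_atoms) if (self.mask >> i) & 1]

    def size(self) -> int:
        return int(self.mask).bit_count()

    def contains(self, atom: int) -> bool:
        return bool((self.mask >> atom) & 1)


def full_subset(mol: Molecule) -> AtomSubset:
    return AtomSubset((1 << mol.n_atoms) - 1, mol.n_atoms)


def _component_masks(n: int, neighbor_lists: List[List[Tuple[int, int]]], removed: Set[int]) -> List[int]:
    """Connected-component bitmasks with the ``removed`` bond ids cut."""
    unvisited = (1 << n) - 1
    comps = []
    while unvisited:
        start_bit = unvisited & -unvisited
        comp = start_bit
        stack = [start_bit.bit_length() - 1]
        unvisited ^= start_bit
        while stack:
            i = stack.pop()
            for j, bond_id in neighbor_lists[i]:
                bit = 1 << j
                if bond_id in removed or not (unvisited & bit):
                    continue
                unvisited ^= bit
                comp |= bit
                stack.append(j)
        comps.append(comp)
    return comps


def break_bonds(
    mol: Molecule,
    depth: int,
    heavy_bonds_only: bool = False,
    hard_ceiling: int = 2**22,
) -> Set[AtomSubset]:
    """All connected components arising from <= ``depth`` bond removals.

    Every unordered combination of up to ``depth`` eligible bonds is
    removed simultaneously and the resulting components collected (two
    removals are needed to open a ring, so rings are handled exactly).
    Always includes the full-molecule subset.  Deduplicated by mask; the
    result for depth ``d`` is a superset of the result for ``d - 1``.
    """
    n = mol.n_atoms
    neighbor_lists: List[List[Tuple[int, int]]] = [[] for _ in range(n)]
    for bond_id, (i, j, _) in enumerate(mol.bonds):
        neighbor_lists[i].append((j, bond_id))
        neighbor_lists[j].append((i, bond_id))
    eligible = [
        bond_id
        for bond_id, (i, j, _) in enumerate(mol.bonds)
        if not heavy_bonds_only or (mol.atoms[i] != "H" and mol.atoms[j] != "H")
    ]
    seen: Set[int] = {(1 << n) - 1}
    for k in range(1, depth + 1):
        for combo in itertools.combinations(eligible, k):
            seen.update(_component_masks(n, neighbor_lists, set(combo)))
            if len(seen) > hard_ceiling:
                raise SubsetOverflowError(
                    f"more than {hard_ceiling} subsets at depth {depth}"
                )
    return {AtomSubset(m, n) for m in seen}


def hydrogen_mask(mol: Molecule) -> int:
    h = 0
    for i, sym in enumerate(mol.atoms):
        if sym == "H":
            h |= 1 << i
    return h


def _bit_combinations(bits: int, max_k: int) -> List[int]:
    """All submasks of ``bits`` with popcount <= max_k (including 0)."""
    idx = [i for i in range(bits.bit_length()) if (bits >> i) & 1]
    out = [0]
    for k in range(1, min(max_k, len(idx)) + 1):
        for combo in itertools.combinations(idx, k):
            m = 0
            for i in combo:
                m |= 1 << i
            out.append(m)
    return out


def hydrogen_rearrange(
    subsets: Iterable[AtomSubset],
    mol: Molecule,
    max_h_transfer: int = 2,
    hard_ceiling: int = 2**22,
) -> Set[AtomSubset]:
    """Augment subsets with every +-hydrogen variant up to ``max_h_transfer``.

    For each input subset, every way of adding up to ``max_h_transfer``
    hydrogen atoms from outside and/or dropping up to ``max_h_transfer``
    hydrogens from inside yields a new subset (distinct hydrogen choices
    are distinct masks).  The output is a superset of the input.
    """
    h_all = hydrogen_mask(mol)
    n = mol.n_atoms
    out: Set[int] = set()
    for sub in subsets:
        out.add(sub.mask)
    if max_h_transfer == 0:
        return {AtomSubset(m, n) for m in out}
    for sub in subsets:
        h_in = sub.mask & h_all
        h_out = h_all & ~sub.mask
        adds = _bit_combinations(h_out, max_h_transfer)
        rems = _bit_combinations(h_in, max_h_transfer)
        for add in adds:
            base = sub.mask | add
            for rem in rems:
                m = base & ~rem
                if m:
                    out.add(m)
        if len(out) > hard_ceiling:
            raise SubsetOverflowError(f"more than {hard_ceiling} subsets after rearrangement")
    return {AtomSubset(m, n) for m in out}


def subsample_subsets(
    subsets: Iterable[AtomSubset], cap: int, seed: int = 0
) -> Set[AtomSubset]:
    """Uniform random cap on the subset collection.

    If the collection fits the cap it is returned unchanged; otherwise a
    uniformly random size-``cap`` sample is drawn (deterministic given
    ``seed``) that always retains the full-molecule subset.
    """
    if cap <= 0:
        raise ValueError("cap must be positive")
    pool = sorted(subsets)  # deterministic base order
    if len(pool) <= cap:
        return set(pool)
    n = pool[0].n_atoms
    full = (1 << n) - 1
    rest = [s for s in pool if s.mask != full]
    rng = np.random.default_rng(seed)
    keep_n = cap - 1 if len(rest) < len(pool) else cap
    picked = rng.choice(len(rest), size=keep_n, replace=False)
    chosen = {rest[i] for i in picked}
    if len(rest) < len(pool):
        chosen.add(AtomSubset(full, n))
    return chosen


def subset_formula(subset: AtomSubset, mol: Molecule) -> Formula:
    """Element counts of the masked atoms."""
    counts = [0] * len(ELEMENTS)
    m = subset.mask
    while m:
        bit = m & -m
        m ^= bit
        counts[UNIVERSE.index(mol.atoms[bit.bit_length() - 1])] += 1
    return Formula(tuple(counts))


def indicator_matrix(
    subsets: Iterable[AtomSubset], mol: Molecule
) -> Tuple[np.ndarray, List[AtomSubset]]:
    """(N_S x N_A) 0/1 matrix, one row per unique subset in sorted-mask order.

    Returns the matrix together with the row-aligned subset list.
    """
    ordered = sorted(set(subsets))
    if not ordered:
        raise ValueError("empty subset collection")
    mat = np.zeros((len(ordered), mol.n_atoms), dtype=np.float64)
    for r, sub in enumerate(ordered):
        for i in sub.indices():
            mat[r, i] = 1.0
    return mat, ordered


def generate_subsets(
    mol: Molecule, config: FragmentationConfig = FragmentationConfig()
) -> Set[AtomSubset]:
    """Full pipeline: break bonds, rearrange hydrogens, filter, cap."""
    subs = break_bonds(
        mol, config.depth, config.heavy_bonds_only, config.hard_ceiling
    )
    if config.hydrogen_rearrangement:
        subs = hydrogen_rearrange(subs, mol, config.max_h_transfer, config.hard_ceiling)
    if not config.keep_single_hydrogens:
        h_all = hydrogen_mask(mol)
        subs = {
            s
            for s in subs
            if not (s.size() == 1 and s.mask & h_all)
        }
    if config.max_subsets is not None and len(subs) > config.max_subsets:
        subs = subsample_subsets(subs, config.max_subsets, config.seed)
    return subs
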