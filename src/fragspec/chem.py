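"""Molecule graphs: parsing, adjacency, atom features, folds, filters.

Molecules are parsed with RDKit and then frozen into a plain
:class:`Molecule` value object — a labelled graph of atoms (element
symbol, 0-based index) and undirected bonds with order in {1, 1.5, 2, 3}.
Hydrogens are always materialised as explicit atoms so that downstream
atom subsets can include or exclude individual hydrogens (required by
hydrogen rearrangement).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator

from .elements import ELEMENTS, UNIVERSE, UnsupportedElementError
from .formulas import Formula, subformula_count

BOND_ORDERS = (1.0, 1.5, 2.0, 3.0)


class MoleculeParseError(ValueError):
    """Input text could not be parsed in the named format."""


@dataclass(frozen=True)
class Molecule:
    """A molecule as a labelled graph with explicit hydrogens.

    ``atoms[i]`` is the element symbol of atom ``i``; ``bonds`` holds each
    undirected bond once as ``(i, j, order)`` with ``i < j``.
    """

    atoms: Tuple[str, ...]
    bonds: Tuple[Tuple[int, int, float], ...]
    smiles: Optional[str] = None

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def n_bonds(self) -> int:
        return len(self.bonds)

    def formula(self) -> Formula:
        counts = [0] * len(ELEMENTS)
        for sym in self.atoms:
            counts[UNIVERSE.index(sym)] += 1
        return Formula(tuple(counts))

    def neighbors(self) -> List[List[int]]:
        adj: List[List[int]] = [[] for _ in range(self.n_atoms)]
        for i, j, _ in self.bonds:
            adj[i].append(j)
            adj[j].append(i)
        return adj

    def heavy_atom_count(self) -> int:
        return sum(1 for s in self.atoms if s != "H")


def _from_rdkit(rdmol: "Chem.Mol", smiles: Optional[str] = None) -> Molecule:
    rdmol = Chem.AddHs(rdmol)
    atoms = []
    for atom in rdmol.GetAtoms():
        sym = atom.GetSymbol()
        if sym not in ELEMENTS:
            raise UnsupportedElementError(sym)
        atoms.append(sym)
    bonds = []
    for bond in rdmol.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        order = bond.GetBondTypeAsDouble()
        if order not in BOND_ORDERS:
            raise MoleculeParseError(f"unsupported bond order {order}")
        bonds.append((min(i, j), max(i, j), order))
    bonds.sort()
    return Molecule(tuple(atoms), tuple(bonds), smiles=smiles)


def parse_molecule(text: str, fmt: str = "smiles") -> Molecule:
    """Parse a SMILES string or a MOL (V2000) block into a :class:`Molecule`.

    Explicit hydrogens are added; atom ordering is the RDKit order for the
    given input string, which is deterministic per input.
    """
    if fmt == "smiles":
        rdmol = Chem.MolFromSmiles(text)
        if rdmol is None:
            raise MoleculeParseError(f"invalid SMILES: {text!r}")
        return _from_rdkit(rdmol, smiles=text)
    if fmt in ("mol", "sdf", "molblock"):
        rdmol = Chem.MolFromMolBlock(text)
        if rdmol is None:
            raise MoleculeParseError("invalid MOL block")
        return _from_rdkit(rdmol)
    raise ValueError(f"unknown format {fmt!r}; use 'smiles' or 'mol'")


def build_adjacency(mol: Molecule) -> np.ndarray:
    """Symmetric N_A x N_A matrix; entry is the bond order, 0 if unbonded."""
    a = np.zeros((mol.n_atoms, mol.n_atoms), dtype=np.float64)
    for i, j, order in mol.bonds:
        a[i, j] = order
        a[j, i] = order
    return a


#: Atom feature layout: element one-hot (8), heavy-degree one-hot (0..4),
#: attached-H count, aromatic flag, in-ring flag, formal charge slot.
FEATURE_NAMES: Tuple[str, ...] = tuple(
    [f"element_{e}" for e in ELEMENTS]
    + [f"degree_{d}" for d in range(5)]
    + ["n_hydrogens", "is_aromatic", "in_ring", "formal_charge"]
)


def atom_features(mol: Molecule) -> np.ndarray:
    """Per-atom input features, one row per atom, in atom-index order.

    Degree counts heavy neighbours only; ring membership and aromaticity
    are derived from the graph (an atom is aromatic iff it has an
    order-1.5 bond; ring membership via cycle detection on the graph).
    Formal charge is always 0 for the neutral molecules in scope but the
    slot is kept so the layout is stable.
    """
    n = mol.n_atoms
    feats = np.zeros((n, len(FEATURE_NAMES)), dtype=np.float64)
    adj = mol.neighbors()
    aromatic = np.zeros(n, dtype=bool)
    for i, j, order in mol.bonds:
        if order == 1.5:
            aromatic[i] = aromatic[j] = True
    in_ring = _ring_membership(mol)
    for i, sym in enumerate(mol.atoms):
        feats[i, UNIVERSE.index(sym)] = 1.0
        heavy_deg = sum(1 for j in adj[i] if mol.atoms[j] != "H")
        feats[i, 8 + min(heavy_deg, 4)] = 1.0
        feats[i, 13] = sum(1 for j in adj[i] if mol.atoms[j] == "H")
        feats[i, 14] = float(aromatic[i])
        feats[i, 15] = float(in_ring[i])
        feats[i, 16] = 0.0
    return feats


def _ring_membership(mol: Molecule) -> np.ndarray:
    """Atoms on some cycle: repeatedly strip degree-<=1 vertices; survivors ring."""
    deg = np.zeros(mol.n_atoms, dtype=int)
    adj = mol.neighbors()
    for i, nbrs in enumerate(adj):
        deg[i] = len(nbrs)
    alive = np.ones(mol.n_atoms, dtype=bool)
    stack = [i for i in range(mol.n_atoms) if deg[i] <= 1]
    while stack:
        i = stack.pop()
        if not alive[i]:
            continue
        alive[i] = False
        for j in adj[i]:
            if alive[j]:
                deg[j] -= 1
                if deg[j] <= 1:
                    stack.append(j)
    return alive


_MORGAN = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=2048)


def dataset_fold(mol: Molecule) -> int:
    """Deterministic dataset fold in 0..9 for train/test splitting.

    The canonical form of the molecule is fingerprinted (Morgan, radius 2,
    2048 bits), the bit vector is packed to bytes in bit order, and the
    fold is the last decimal digit of the CRC32 checksum of those bytes.
    Any SMILES spelling of the same molecule lands in the same fold, which
    also groups duplicate rows of a dataset into one fold.
    """
    rdmol = Chem.MolFromSmiles(Chem.MolToSmiles(_to_rdkit(mol)))
    fp = _MORGAN.GetFingerprint(rdmol)
    bits = np.zeros(2048, dtype=np.uint8)
    for b in fp.GetOnBits():
        bits[b] = 1
    data = np.packbits(bits).tobytes()
    return zlib.crc32(data) % 10


def _to_rdkit(mol: Molecule) -> "Chem.Mol":
    """Rebuild an RDKit molecule from the frozen graph."""
    if mol.smiles is not None:
        rd = Chem.MolFromSmiles(mol.smiles)
        if rd is not None:
            return rd
    em = Chem.RWMol()
    for sym in mol.atoms:
        em.AddAtom(Chem.Atom(sym))
    order_map = {
        1.0: Chem.BondType.SINGLE,
        1.5: Chem.BondType.AROMATIC,
        2.0: Chem.BondType.DOUBLE,
        3.0: Chem.BondType.TRIPLE,
    }
    for i, j, order in mol.bonds:
        em.AddBond(i, j, order_map[order])
    rd = em.GetMol()
    Chem.SanitizeMol(rd)
    return rd


def canonical_smiles(mol: Molecule) -> str:
    return Chem.MolToSmiles(Chem.RemoveHs(_to_rdkit(mol)))


@dataclass(frozen=True)
class FilterResult:
    passed: bool
    reason: Optional[str] = None  # "atoms" | "formulae" | "subsets"

    def __bool__(self) -> bool:
        return self.passed


def passes_filters(
    mol: Molecule,
    max_atoms: int = 48,
    max_formulae: int = 4096,
    max_subsets: int = 12288,
    depth: int = 3,
    hydrogen_rearrangement: bool = True,
) -> FilterResult:
    """Training-set admission filter.

    A molecule passes iff its total atom count is <= ``max_atoms``, its
    unique-subformula count is <= ``max_formulae``, and the number of atom
    subsets generated at the given fragmentation settings is
    <= ``max_subsets``.  Checks are ordered cheapest first and the first
    violated one is reported.
    """
    if mol.n_atoms > max_atoms:
        return FilterResult(False, "atoms")
    if subformula_count(mol.formula()) > max_formulae:
        return FilterResult(False, "formulae")
    from .fragments import FragmentationConfig, generate_subsets

    cfg = FragmentationConfig(
        depth=depth,
        hydrogen_rearrangement=hydrogen_rearrangement,
        max_subsets=None,  # count before capping
    )
    subsets = generate_subsets(mol, cfg)
    if len(subsets) > max_subsets:
        return FilterResult(False, "subsets")
    return FilterResult(True)
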