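"""Synthetic (molecule, spectrum) data with known ground truth.

Real EI-MS libraries are licensed, so testability rests on synthetic
data whose generative process is the package's own observation model
run forward from a *planted* fragment distribution:

1. small random molecules over {C, H, O, N} are grown atom by atom
   under valence constraints;
2. a planted model scores each fragment formula reachable by the subset
   enumeration with a fixed random linear function of cheap descriptors
   (element counts, fragment size, H-count parity) and softmaxes the
   scores into a distribution;
3. the spectrum is the exact observation-model rendering of that
   distribution, optionally degraded into noisy "replicate" copies
   (log-normal intensity jitter + peak dropout) for the matching task.

Descriptors use only formula-level information, so the planted targets
are realizable by both the formula head and the subset head, and
training can in principle drive the loss to zero.  Everything is a pure
function of the seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np
from rdkit import Chem
from rdkit.rdBase import BlockLogs

from .chem import Molecule, canonical_smiles, parse_molecule, passes_filters
from .elements import VALENCE
from .formulas import Formula
from .fragments import FragmentationConfig, generate_subsets, subset_formula
from .spectrum import FragmentProbabilities, Spectrum, assemble_spectrum, normalize

_HEAVY = ("C", "O", "N")
_HEAVY_WEIGHTS = (0.7, 0.15, 0.15)


class MoleculeCountError(RuntimeError):
    """Could not produce the requested number of distinct molecules."""


def _random_heavy_graph(rng: np.random.Generator, n_heavy: int) -> Optional[str]:
    """Grow a random valence-respecting heavy-atom graph; return SMILES."""
    symbols = list(rng.choice(_HEAVY, size=n_heavy, p=_HEAVY_WEIGHTS))
    free = [VALENCE[s] for s in symbols]
    em = Chem.RWMol()
    for s in symbols:
        em.AddAtom(Chem.Atom(s))
    bonded: List[Tuple[int, int]] = []
    for i in range(1, n_heavy):
        candidates = [j for j in range(i) if free[j] >= 1]
        if not candidates:
            return None
        j = int(candidates[rng.integers(len(candidates))])
        order = 1
        if free[i] >= 2 and free[j] >= 2 and rng.random() < 0.15:
            order = 2
        em.AddBond(i, j, Chem.BondType.DOUBLE if order == 2 else Chem.BondType.SINGLE)
        free[i] -= order
        free[j] -= order
        bonded.append((min(i, j), max(i, j)))
    # occasional ring closure
    if n_heavy >= 3 and rng.random() < 0.35:
        pairs = [
            (i, j)
            for i in range(n_heavy)
            for j in range(i + 1, n_heavy)
            if free[i] >= 1 and free[j] >= 1 and (i, j) not in bonded
        ]
        if pairs:
            i, j = pairs[int(rng.integers(len(pairs)))]
            em.AddBond(i, j, Chem.BondType.SINGLE)
    mol = em.GetMol()
    with BlockLogs():
        try:
            Chem.SanitizeMol(mol)
        except Exception:
            return None
    return Chem.MolToSmiles(mol)


def enumerate_toy_molecules(
    max_heavy_atoms: int = 8,
    n: int = 100,
    seed: int = 0,
    check_filters: bool = True,
    max_attempts_factor: int = 200,
) -> List[Molecule]:
    """``n`` distinct random {C,H,O,N} molecules, deterministic given ``seed``.

    Every returned molecule parses, is connected, has at most
    ``max_heavy_atoms`` heavy atoms (capped at 10 so exhaustive oracles
    stay feasible), and passes the default dataset filters.
    """
    if max_heavy_atoms > 10:
        raise ValueError("max_heavy_atoms must be <= 10")
    rng = np.random.default_rng(seed)
    seen = set()
    out: List[Molecule] = []
    attempts = 0
    max_attempts = max_attempts_factor * n
    while len(out) < n:
        attempts += 1
        if attempts > max_attempts:
            raise MoleculeCountError(
                f"only found {len(out)} of {n} distinct molecules "
                f"after {attempts} attempts"
            )
        n_heavy = int(rng.integers(2, max_heavy_atoms + 1))
        smiles = _random_heavy_graph(rng, n_heavy)
        if smiles is None or smiles in seen:
            continue
        seen.add(smiles)
        try:
            mol = parse_molecule(smiles)
        except ValueError:
            continue
        if check_filters and not passes_filters(mol):
            continue
        out.append(mol)
    return out


#: descriptor layout: 8 normalized element counts, fragment size, H parity
_N_DESCRIPTORS = 10


@dataclass(frozen=True)
class PlantedModel:
    """Ground-truth fragment propensities: a fixed random linear score over
    formula descriptors, softmaxed at the given temperature.

    ``temperature=0`` gives the uniform distribution over candidates.
    """

    seed: int = 0
    temperature: float = 1.0

    def weights(self) -> np.ndarray:
        return np.random.default_rng(self.seed).normal(0.0, 1.0, size=_N_DESCRIPTORS)

    def descriptors(self, formula: Formula) -> np.ndarray:
        counts = np.array(formula.counts, dtype=np.float64)
        return np.concatenate(
            [counts / 4.0, [formula.total_atoms / 10.0], [formula.count("H") % 2]]
        )

    def distribution(self, formulas: Sequence[Formula]) -> np.ndarray:
        w = self.weights()
        logits = self.temperature * np.array(
            [w @ self.descriptors(f) for f in formulas]
        )
        logits -= logits.max()
        p = np.exp(logits)
        return p / p.sum()


def planted_spectrum(
    mol: Molecule,
    planted: PlantedModel,
    resolution: float = 1.0,
    frag_config: FragmentationConfig = FragmentationConfig(),
    prune_below: float = 1e-6,
) -> Tuple[Spectrum, FragmentProbabilities]:
    """Ground-truth spectrum and the fragment distribution that produced it.

    The support is the set of distinct fragment formulas reachable by
    subset enumeration, so the target is realizable by both heads.
    """
    subs = generate_subsets(mol, frag_config)
    formulas = sorted({subset_formula(s, mol) for s in subs})
    probs = planted.distribution(formulas)
    fp = FragmentProbabilities(list(zip(formulas, probs.tolist())))
    spec = assemble_spectrum(fp, mol, resolution, prune_below)
    return spec, fp


@dataclass(frozen=True)
class ReplicateNoise:
    """Run-to-run measurement noise: multiplicative log-normal intensity
    jitter and Bernoulli peak dropout."""

    jitter: float = 0.1
    dropout: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if self.jitter < 0 or not 0 <= self.dropout < 1:
            raise ValueError("require jitter >= 0 and dropout in [0, 1)")


def make_replicates(
    spec: Spectrum, noise: ReplicateNoise, count: int = 1
) -> List[Spectrum]:
    """Noisy replicate measurements of a spectrum, L2-renormalized.

    The base peak is never dropped, so every replicate stays non-empty.
    """
    rng = np.random.default_rng(noise.seed)
    base = int(np.argmax(spec.intensity))
    out = []
    for _ in range(count):
        factors = np.exp(rng.normal(0.0, noise.jitter, size=len(spec)))
        keep = rng.random(len(spec)) >= noise.dropout
        keep[base] = True
        intens = spec.intensity * factors * keep
        rep = Spectrum(spec.bin_index[intens > 0], intens[intens > 0], spec.resolution)
        out.append(normalize(rep, "L2"))
    return out


def make_dataset(
    n: int = 100,
    max_heavy_atoms: int = 8,
    seed: int = 0,
    resolution: float = 1.0,
    temperature: float = 1.0,
    frag_config: FragmentationConfig = FragmentationConfig(),
) -> List[Tuple[Molecule, Spectrum, FragmentProbabilities]]:
    """Convenience: molecules + planted spectra + ground-truth distributions."""
    mols = enumerate_toy_molecules(max_heavy_atoms, n, seed)
    planted = PlantedModel(seed=seed + 1, temperature=temperature)
    out = []
    for mol in mols:
        spec, fp = planted_spectrum(mol, planted, resolution, frag_config)
        out.append((mol, spec, fp))
    return out
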