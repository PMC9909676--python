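"""Atom-subset enumeration: bond breaking, H rearrangement, capping."""

import itertools

import networkx as nx
import numpy as np
import pytest

import fragspec as fs
from fragspec.fragments import full_subset, hydrogen_mask


def brute_force_break(mol, depth):
    """Independent oracle: enumerate every combination of <= depth removed
    bonds explicitly and collect connected-component atom sets via networkx."""
    g = nx.Graph()
    g.add_nodes_from(range(mol.n_atoms))
    g.add_edges_from([(i, j) for i, j, _ in mol.bonds])
    masks = {frozenset(range(mol.n_atoms))}
    edges = list(g.edges())
    for k in range(1, depth + 1):
        for removed in itertools.combinations(edges, k):
            h = g.copy()
            h.remove_edges_from(removed)
            for comp in nx.connected_components(h):
                masks.add(frozenset(comp))
    return {frozenset(m) for m in masks}


def as_index_sets(subsets):
    return {frozenset(s.indices()) for s in subsets}


class TestBreakBonds:
    def test_depth_zero_is_full_molecule(self, ethanol):
        subs = fs.break_bonds(ethanol, 0)
        assert subs == {full_subset(ethanol)}

    def test_ethane_depth_one_matches_oracle(self, ethane):
        got = as_index_sets(fs.break_bonds(ethane, 1))
        want = brute_force_break(ethane, 1)
        assert got == want
        # one C-C break (2 CH3 masks) + six C-H breaks (6 H + 6 C2H5 masks)
        assert len(got) == 1 + 14

    @pytest.mark.parametrize("smiles", ["CCO", "C1CC1", "C=CC", "OC=O"])
    @pytest.mark.parametrize("depth", [1, 2])
    def test_small_molecules_match_oracle(self, smiles, depth):
        mol = fs.parse_molecule(smiles)
        if mol.n_bonds <= 8 or depth <= 2:
            assert as_index_sets(fs.break_bonds(mol, depth)) == brute_force_break(
                mol, depth
            )

    def test_depth_monotonicity(self, toy_molecules):
        for mol in toy_molecules:
            prev = set()
            for d in range(4):
                cur = fs.break_bonds(mol, d)
                assert prev <= cur
                prev = cur

    def test_heavy_only_restriction(self, ethane):
        subs = fs.break_bonds(ethane, 1, heavy_bonds_only=True)
        # only the C-C bond is eligible: full + two CH3 fragments
        assert len(subs) == 3


class TestHydrogenRearrange:
    def test_zero_transfer_is_identity(self, ethane):
        subs = fs.break_bonds(ethane, 1)
        assert fs.hydrogen_rearrange(subs, ethane, 0) == subs

    def test_ch3_gains_and_loses_one_hydrogen(self, ethane):
        # take one CH3 fragment from the C-C break
        ch3 = next(
            s
            for s in fs.break_bonds(ethane, 1)
            if fs.subset_formula(s, ethane) == fs.Formula.from_string("CH3")
        )
        out = fs.hydrogen_rearrange({ch3}, ethane, 1)
        formulas = sorted(str(fs.subset_formula(s, ethane)) for s in out)
        # 3x CH2 (each dropped H distinct), 3x CH4 (each gained H distinct),
        # and 10x CH3: the original plus 3x3 single-H swaps (one in, one out)
        assert formulas.count("CH2") == 3
        assert formulas.count("CH4") == 3
        assert formulas.count("CH3") == 10
        assert ch3 in out

    def test_superset_contract(self, toy_molecules):
        for mol in toy_molecules[:5]:
            subs = fs.break_bonds(mol, 2)
            out = fs.hydrogen_rearrange(subs, mol, 2)
            assert subs <= out


class TestSubsample:
    def test_under_cap_unchanged(self, ethane):
        subs = fs.break_bonds(ethane, 1)
        assert fs.subsample_subsets(subs, cap=100, seed=0) == subs

    def test_capped_and_deterministic(self, toy_molecules):
        mol = toy_molecules[0]
        subs = fs.generate_subsets(mol, fs.FragmentationConfig(max_subsets=None))
        a = fs.subsample_subsets(subs, cap=10, seed=5)
        b = fs.subsample_subsets(subs, cap=10, seed=5)
        assert a == b and len(a) == 10

    def test_full_molecule_always_retained(self, toy_molecules):
        mol = toy_molecules[1]
        subs = fs.generate_subsets(mol, fs.FragmentationConfig(max_subsets=None))
        capped = fs.subsample_subsets(subs, cap=5, seed=1)
        assert full_subset(mol) in capped


class TestSubsetFormula:
    def test_full_molecule_formula(self, ethanol):
        assert fs.subset_formula(full_subset(ethanol), ethanol) == ethanol.formula()

    def test_symmetric_ch3_distinct_masks_same_formula(self, ethane):
        ch3s = [
            s
            for s in fs.break_bonds(ethane, 1)
            if fs.subset_formula(s, ethane) == fs.Formula.from_string("CH3")
        ]
        assert len(ch3s) == 2 and ch3s[0].mask != ch3s[1].mask

    def test_formulas_stay_inside_subformula_lattice(self, toy_molecules):
        for mol in toy_molecules[:6]:
            lattice = {f.counts for f in fs.enumerate_subformulae(mol.formula())}
            subs = fs.generate_subsets(mol, fs.FragmentationConfig(max_subsets=512))
            for s in subs:
                assert fs.subset_formula(s, mol).counts in lattice


class TestIndicatorMatrix:
    def test_methane_full_subset(self, methane):
        mat, order = fs.indicator_matrix({full_subset(methane)}, methane)
        assert mat.shape == (1, 5) and (mat == 1).all()

    def test_row_count_matches_dedup(self, ethane):
        subs = fs.break_bonds(ethane, 1)
        mat, order = fs.indicator_matrix(subs, ethane)
        assert mat.shape[0] == len(subs)
        assert len({tuple(r) for r in mat}) == mat.shape[0]

    def test_distinct_formula_coverage_monotone_in_depth(self, toy_molecules):
        # coverage of distinct fragment formulas grows with depth, and
        # hydrogen rearrangement only adds coverage
        for mol in toy_molecules[:4]:
            prev = set()
            for d in range(3):
                subs = fs.break_bonds(mol, d)
                cover = {fs.subset_formula(s, mol) for s in subs}
                assert prev <= cover
                prev = cover
            with_hr = fs.hydrogen_rearrange(
                fs.break_bonds(mol, 2), mol, 2
            )
            assert prev <= {fs.subset_formula(s, mol) for s in with_hr}
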