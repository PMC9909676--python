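"""Enumerate the fragment candidates of a molecule.

Two candidate spaces feed the models: the exhaustive subformula lattice
(every element-count vector dominated by the molecular formula) and the
atom subsets generated by depth-d bond breaking plus hydrogen
rearrangement.
"""

import fragspec as fs

glucose = fs.Formula.from_string("C6H12O6")
fset = fs.enumerate_subformulae(glucose)
print(f"C6H12O6 has {len(fset)} subformulae "
      f"(7 x 13 x 7 over the C, H, O count ranges)")

ethanol = fs.parse_molecule("CCO")
print(f"\nethanol: {ethanol.n_atoms} atoms, {ethanol.n_bonds} bonds")
for depth in range(4):
    subs = fs.break_bonds(ethanol, depth)
    formulas = {fs.subset_formula(s, ethanol) for s in subs}
    print(f"  depth {depth}: {len(subs):4d} atom subsets, "
          f"{len(formulas):3d} distinct fragment formulas")

with_hr = fs.hydrogen_rearrange(fs.break_bonds(ethanol, 3), ethanol, 2)
print(f"  depth 3 + hydrogen rearrangement (+-2 H): {len(with_hr)} subsets")
print("\nDeeper breaking and H transfer only ever widen the candidate pool;")
print("every subset's formula stays inside the exhaustive subformula lattice.")
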