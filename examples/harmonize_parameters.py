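"""Harmonize the term energies of a carbohydrate parameter file.

NMR annealing protocols expect the covalent-geometry force constants used
for proteins and nucleic acids (BOND 1000, ANGLE 500, IMPROPER 500,
DIHEDRAL 2, kcal/mol units); carbohydrate files shipped for crystallography
carry much weaker constants, letting experimental restraints bend sugar
geometry.  This script builds a small random parameter set, harmonizes it,
and shows the constants before and after.
"""

import glycotop as gt

before = gt.make_random_parameters(seed=1)
after = gt.harmonize_energies(before)

print("bond k before :", sorted({p.k for p in before.bonds}))
print("bond k after  :", sorted({p.k for p in after.bonds}))
print("angle k after :", sorted({p.k for p in after.angles}))
print("dihedral k    :", sorted({p.k for p in after.dihedrals}))
print("b0 preserved  :", [p.b0 for p in after.bonds] == [p.b0 for p in before.bonds])

print("\nEmitted file head:")
print("\n".join(gt.write_parameters(after).splitlines()[:5]))
# Every force constant is now uniform while equilibrium geometry is
# untouched, so restraint energies can no longer out-muscle covalent terms.
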