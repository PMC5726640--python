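# Methods

## The problem

NMR structure calculation programs build structures by simulated annealing
under a hybrid energy: covalent-geometry terms (BOND, ANGLE, DIHEDRAL,
IMPROPER) read from topology/parameter files, plus experimental restraint
terms. The carbohydrate files distributed with the common structure-
calculation engines were written for crystallographic refinement, and three
defects surface the moment they meet a standard annealing protocol:

1. **Missing parameters.** Instantiating the N-acetyl amide impropers of
   GlcNAc-type residues hits type tuples with no parameter entry and aborts
   the run.
2. **Weak force constants.** Some carbohydrate ANGLE energies are smaller
   than the experimental-restraint force constants, so restraints bend
   sugar geometry away from ideality.
3. **Heavy-atom chirality impropers.** Ring-carbon chirality enforced by an
   improper over the central carbon and its heavy-atom neighbours leaves
   the bonded hydrogen energetically unconstrained in the improper term;
   annealing can deposit it mirror-reflected through the carbon
   ("flipped"), and minimization cannot recover.

`glycotop` implements the corresponding file transformations as executable
operations, adds the O-/S-glycosylation patch catalogue, and ships a small
annealing engine plus ensemble-analysis toolkit that demonstrate and
validate the fixes quantitatively.

## The flip trap, quantitatively

Let C be a chiral ring carbon, H its hydrogen, and consider reflecting H
through C along the C–H line (H → 2C − H). Every heavy-atom-only improper
is numerically unchanged by this move (no term contains H). Bond angles
H–C–X change from θ₀ to 180° − θ₀, but along the reflection *line* their
gradient components cancel by symmetry, so the flipped state is a genuine
stationary point; the only energy that varies along the line is the C–H
bond term, which has minima at both ±|CH| and a wall of height
k_bond·|CH|² ≈ 1000 × 1.09² ≈ 1.2·10³ kcal/mol at the carbon. The package
asserts all of this programmatically: the heavy-only minimization endpoint
is gradient-converged (‖g‖ ≤ 10⁻³) with the chirality violation intact,
and a 201-point scan of H along the C–H line shows an interior maximum
(~1164 kcal/mol above the endpoints with the default fixture).

The fix replaces each chirality improper with one over the **four
substituent vertices** (hydrogen first, then remaining substituents by
descending atomic number, then name — a fixed ordering so targets are
reproducible). On an ideal tetrahedral center this improper measures
±arccos(1/3) = ±70.53°, and reflecting the hydrogen flips its sign, so the
flipped state now carries an improper penalty of order
k·(140° in rad)² ≈ 3·10³ kcal/mol and stops being a minimum. The same
minimization then ends with zero violations, and Metropolis annealing
recovers correct chirality in 20/20 seeded replicates.

### Sign conventions

Torsions follow the IUPAC convention, computed as
`atan2(|b₂| b₁·(b₂×b₃), (b₁×b₂)·(b₂×b₃))`. Note the torsion is *invariant*
under reversing the four points (it looks the same from either end of the
central bond) and is *negated* by mirror reflection; the test suite pins
both properties, because the second one is exactly what makes a single
signed improper a chirality detector. Anomeric configuration is encoded
once, package-wide: for the (H1, O5, C2, X) improper at C1 of a D-sugar,
alpha ↦ −70.53°, beta ↦ +70.53°, with L-sugars mirrored. The choice of
which hand is called "alpha" is a convention (no numeric value is printed
anywhere upstream to anchor it); what is *not* conventional, and is
tested, is that alpha/beta and D/L pairs are mirror images.

## File dialect

The parser covers the topology/parameter dialect subset that carbohydrate
files actually use: `RESIdue`/`PRESidue` blocks, `ATOM` (with `TYPE=`,
`CHARge=`, `MASS=`), `BOND`, `ANGLe`, `DIHEdral`, `IMPRoper`, patch edits
(`ADD`, `DELEte`, `MODIfy`), `GROUp`, `MASS`, `AUTOGENERATE`, `!` comments,
backslash continuation, keywords matched case-insensitively on their first
four characters. Unknown statements are preserved verbatim and re-emitted
in place, so files embedded in larger distributions round-trip without
loss. Parameter lookups are symmetric (bond pairs, angle/torsion reversal)
with exact-before-wildcard precedence; duplicate identical tuples resolve
last-one-wins with a logged warning.

One deliberate dialect extension: improper statements accept an optional
`TARGet=<degrees>` field. Chirality impropers *must* carry their target
geometry individually — the two mirror forms of a center share one
atom-type tuple, so a type-keyed parameter file cannot distinguish them.
Patches generated by the catalogue use this field for the anomeric
improper; plain type-keyed impropers work exactly as before.

## Energy model

Functional forms (file convention, `k·Δ²` with no ½ factor; file units
kcal/mol, Å, degrees; radians internally):

* bond `k(b−b₀)²`, angle `k(θ−θ₀)²`
* dihedral `k(1+cos(nφ−δ))` for periodicity n>0, harmonic `k·Δφ²` for n=0
* improper: harmonic in the minimal-image difference to φ₀ (wraps at ±180°)
* nonbonded: repulsion only, `E = k_rep·(max(0,(s·σᵢⱼ)²−r²))²` with
  k_rep = 4.0 kcal·mol⁻¹·Å⁻⁴, scale s = 0.8, σᵢⱼ the arithmetic mean of
  per-type sigmas; 1-2 and 1-3 pairs excluded, 1-4 and beyond at full
  weight. No charges, no attraction — the conventional annealing choice.

Gradients are analytic (Blondel–Karplus-style torsion derivatives) and are
held to <10⁻⁶ relative agreement with central finite differences in the
test suite; energies are held to <10⁻¹² relative agreement with a literal
scalar transcription of the forms above.

The harmonized constants are 1000.0 (bond), 500.0 (angle), 500.0
(improper), 2.0 (dihedral) — the protein/nucleic-acid values a standard
annealing protocol assumes. A configuration check asserts the angle
constant is not below typical experimental-restraint constants (~50 for
NOE wells, ~200 for dihedral restraints), which is the reason
harmonization exists. The small dihedral constant is intentional:
conformational torsions must stay soft.

## Minimizer and annealer

The minimizer is steepest descent along −g with Armijo backtracking;
the trial step length is the Barzilai–Borwein estimate, because a fixed
step zig-zags badly on a surface whose stiffness spans k = 1000 (bonds) to
k = 2 (torsions) and needed >15k iterations to converge the trapped state.
Energy never increases across accepted steps. The annealer is Metropolis
with single-atom Gaussian displacement proposals (σ = 0.05 Å) under
geometric cooling, default schedule t_high = 50 → t_low = 0.5 on the
kcal/mol scale over 5000 steps (3000 in the replicate experiments, which
is enough at fixture scale), bit-for-bit reproducible per (seed, schedule).
This engine is deliberately *not* the production protocol — no
torsion-angle dynamics, no restraint energy classes, no multi-stage
cooling — it exists to exhibit the trap mechanism and its fix on the
fixture, and nothing in the package claims to regenerate recalculated
deposition ensembles.

## The synthetic pyranose

The fixture is a schematic sugar: an O5,C1–C5 ring, one hydroxyl + one
hydrogen per ring carbon, and an exocyclic CH₂OH arm (giving one achiral
CH₂ as a negative control). Ideal constants: C–C 1.526 Å, C–O 1.420 Å,
C–H 1.090 Å, O–H 0.960 Å, all angles tetrahedral (109.471°); amide/thiol
lengths for the companion residues: C–N 1.470, N–H 1.010, C–S 1.810,
S–H 1.340 Å. An approximate ideal chair (ring torsions ±60°) is relaxed to
the bottom of its own bond/angle/repel surface with L-BFGS (construction
only; the annealer's own minimizer is the contractual one), then dihedral
deltas and improper targets are *measured* from the relaxed geometry — so
the reference conformation has total energy ≈ 0 (below 10⁻⁹ kcal/mol) by
construction rather than by hand-tuning, and every chirality target is
self-consistent. Variants: `flipped_H3` (H3 reflected through C3),
`mirror`, `boat`, `noisy` (0.05 Å Gaussian, seeded).

What the fixture does **not** emulate: real anomeric fine structure,
realistic charges, solvent, or the conformational heterogeneity of real
deposited ensembles. Tests passing on it show the machinery is correct
(parsers, term instantiation, chirality logic, statistics), not that any
particular deposited structure is reproduced.

## Ensemble analyses

* **Glycosidic torsions**: phi = O5–C1–Ox′–Cx′ (default heavy-atom
  convention; an H1-based phi = H1–C1–Ox′–Cx′ option is provided since
  published tables do not always state theirs), psi = C1–Ox′–Cx′–C(x−1)′.
  Acceptor paths are tabulated per linkage chemistry (Ser OG/CB/CA,
  Thr OG1/CB/CA, Cys SG/CB/CA, 1-3/1-4/1-6 sugar linkages). Statistics are
  circular: mean by resultant direction, SD = √(−2 ln R̄) in degrees;
  mean of {179°, −179°} is 180°, asserted.
* **Ensemble RMSD**: default is the mean over all model pairs of the RMSD
  after optimal least-squares superposition on the selection (SVD/Kabsch
  with determinant correction, cross-checked against Horn's quaternion
  method to 10⁻⁹ Å); a `to_mean` mode (iterated mean structure) is one
  flag away, since published tables rarely state which convention they
  used. Values are reported to 0.01 Å (0.0001 Å below 0.005, where tables
  print three decimals).
* **Ring pucker**: Cremer–Pople (Q, θ, φ₂) over the six ring atoms ordered
  O5,C1..C5. Classes by θ band: chair θ<45° or θ>135°; boat/twist-boat
  80°–100° (boat when φ₂ is within 15° of a multiple of 60°); the rest is
  the envelope/half-chair band; Q < 0.05 Å is planar. Standard banding;
  thresholds are classification conveniences, not measurements.
* **Restraint counting**: XPLOR-style `assign (sel) (sel) d d⁻ d⁺`
  statements, a selection sub-language (`segid`, `resid`, `resname`,
  `name`, `and/or/not`, parentheses, `*`/`#`/`%` wildcards). A restraint
  crosses two selections when one member matches each against a supplied
  atom roster; the count is symmetric in its arguments.

## Design choices that were genuinely open

* **Stereocenter scope**: all tetrahedral carbons with four distinct
  substituent environments are retargeted by default (a ring-only switch
  exists), since exocyclic centers suffer the identical trap.
* **Stereocenter detection** uses a depth-3 element-multiset branch
  signature — enough to distinguish substituents on fixture-scale sugars
  without a full canonical-labelling algorithm; it is not CIP and assigns
  no R/S names.
* **Glycosylation patch deletions**: condensation chemistry fixes them as
  sugar O1/HO1 plus the acceptor hydroxyl/thiol hydrogen; one new bond,
  valences stay correct. Patch charges are left untouched (the annealing
  here is geometry-only).
* **Patch reference convention**: group `1-` is the sugar donating C1,
  `2-` the acceptor.
* **Chirality check tolerance**: 25° default. The sign is the diagnostic;
  the tolerance only guards near-planar noise.
* **1,3/1,6-linkage patches** install only the C1 anomeric improper, not
  an acceptor-side one; the acceptor carbon keeps whatever improper its
  residue defines.

## Problem sizes and determinism

All experiments run on the 24-atom fixture: minimizations a few thousand
descent iterations, annealing 3000 Metropolis steps, recovery experiments
20 seeded replicates, line scans 201 points — chosen so the full mechanism
demonstration, including the 20-replicate recovery experiment, completes
in about a minute. Every stochastic operation takes an explicit seed and
is reproducible bit-for-bit; `scripts/acceptance.py` derives all of its
seeds from the single `--seed` argument.

## Known limitations

* The annealing engine is Cartesian single-atom Metropolis plus descent —
  sufficient to exhibit the trap, far from a production protocol; no
  restraint energies exist, so "recalculated" deposition ensembles are out
  of reach by design.
* The dialect parser covers the carbohydrate-file subset, not the full
  statement grammar (no DONOr/ACCEptor semantics, no format conversion to
  other force-field families).
* `read_ensemble` handles PDB only (no mmCIF); linkages are user-specified,
  never auto-detected from coordinates.
* The substituent-signature stereocenter test can in principle miss
  centers whose branches differ only beyond depth 3; for sugar-scale
  residues this does not occur.
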