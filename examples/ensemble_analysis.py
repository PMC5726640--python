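"""Ensemble analyses: glycosidic torsions, sugar RMSD, ring pucker and
restraint counting — the validation toolkit one runs on an NMR ensemble.

Inputs here are constructed so every answer is known exactly; point
read_ensemble at a multi-model PDB file to run the same analyses on a
deposition.
"""

import numpy as np

import glycotop as gt

# --- torsions: build 5 models at known phi/psi and recover the statistics
phis = [-46.5, -44.0, -50.1, -47.3, -45.8]
psis = [92.7, 90.2, 95.5, 93.0, 91.1]
e = gt.make_torsion_ensemble(phis, psis)
link = gt.Linkage.from_kind(("A", 1), ("A", 2), "thr", label="alpha-sugar->Thr")
r = gt.glycosidic_torsions(e, link)
print(f"{r.label}: phi = {r.phi_mean} +/- {r.phi_sd} deg, "
      f"psi = {r.psi_mean} +/- {r.psi_sd} deg over {len(r.phi)} models")
# circular mean/SD of the per-model glycosidic torsions (the two axes of a
# carbohydrate Ramachandran plot)

# --- RMSD: sugar heavy atoms over a jittered 10-model ensemble
bundle = gt.make_pyranose(0)
atoms = [gt.AtomMeta("A", 1, "PYR", a.name, a.element, het=True)
         for a in bundle.molecule.atoms]
rng = np.random.default_rng(0)
models = np.stack([bundle.reference_conformation +
                   rng.normal(scale=0.05, size=bundle.reference_conformation.shape)
                   for _ in range(10)])
rep = gt.ensemble_rmsd(gt.Ensemble(atoms, models),
                       lambda a: a.het and a.element != "H")
print(f"sugar heavy-atom ensemble RMSD: {rep.mean_rmsd} A "
      f"(mean over all superposed model pairs)")

# --- pucker: Cremer-Pople class of the ring in the reference model
names = [a.name for a in bundle.molecule.atoms]
ring = [names.index(n) for n in ("O5", "C1", "C2", "C3", "C4", "C5")]
pk = gt.ring_pucker(bundle.reference_conformation, ring)
print(f"ring pucker: Q={pk.Q:.2f} A, theta={pk.theta:.1f} deg -> {pk.label}")

# --- restraints: how many NOEs tie the sugar to the protein?
table = """
assign (resid 1 and name H1) (resid 50 and name HA) 3.0 0.5 0.5
assign (resid 1 and name H8) (resid 51 and name HB#) 4.0 1.0 1.0
assign (resid 50 and name HN) (resid 51 and name HA) 2.8 0.3 0.3
"""
roster = [gt.AtomMeta("A", 1, "A2G", "H1", "H", het=True),
          gt.AtomMeta("A", 1, "A2G", "H8", "H", het=True),
          gt.AtomMeta("A", 50, "ALA", "HA", "H"),
          gt.AtomMeta("A", 50, "ALA", "HN", "H"),
          gt.AtomMeta("A", 51, "LEU", "HB1", "H"),
          gt.AtomMeta("A", 51, "LEU", "HA", "H")]
recs = gt.parse_distance_restraints(table)
n = gt.count_between(recs, "resname A2G", "not resname A2G", roster)
print(f"restraints crossing sugar/protein: {n} of {len(recs)}")
# few crossing restraints means the sugar's pose is weakly determined and
# its ensemble spread (RMSD above) should be interpreted accordingly
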