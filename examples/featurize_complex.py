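"""Featurize one protein-ligand complex and score it with the Vina composite.

Builds a minimal PDBQT ligand and PDB protein in memory, parses them into
typed heavy atoms, and prints the 6 Vina features, a few of the 36
element-pair counts, and the untrained composite score on the pKd scale.
"""

from vinarf import featurize, vina_score
from vinarf.structio import MolecularComplex, count_rotatable_bonds, parse_pdb, parse_pdbqt

LIGAND = """\
REMARK  2 active torsions:
ATOM      1  C   LIG A   1       0.000   0.000   0.000  1.00  0.00    +0.000 C
ATOM      2  C   LIG A   1       1.500   0.000   0.000  1.00  0.00    +0.000 C
ATOM      3  O   LIG A   1       2.200   1.100   0.000  1.00  0.00    +0.000 OA
ATOM      4  N   LIG A   1      -1.400   0.500   0.300  1.00  0.00    +0.000 N
BRANCH   1   2
BRANCH   2   3
"""

PROTEIN = """\
ATOM      1  N   ALA A   1       4.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       5.200   0.800   0.000  1.00  0.00           C
ATOM      3  C   ALA A   1       6.500   0.000   0.200  1.00  0.00           C
ATOM      4  O   ALA A   1       6.600  -1.200   0.100  1.00  0.00           O
ATOM      5  CB  ALA A   1       5.300   2.100   0.800  1.00  0.00           C
"""

ligand_atoms, torsions = parse_pdbqt(LIGAND, "ligand")
protein_atoms = parse_pdb(PROTEIN, "protein")
cplx = MolecularComplex(
    id="demo",
    protein_atoms=protein_atoms,
    ligand_atoms=ligand_atoms,
    n_rotatable_bonds=count_rotatable_bonds(torsions),
)

fv = featurize(cplx, "vinaelem42")
print("vina6 features (summed pair terms + Nrot):")
for name in ("gauss1", "gauss2", "repulsion", "hydrophobic", "hbond", "nrot"):
    print(f"  {name:12s} {fv[name]:10.4f}")
print("element-pair counts within 12 A (nonzero):")
for name in fv.feature_names[6:]:
    if fv[name] > 0:
        print(f"  {name:6s} {int(fv[name])}")
print(f"Vina composite prediction: {vina_score(cplx):.3f} pKd units")
print("(larger = stronger predicted binding; this toy ligand sits close "
      "enough to clash, so the repulsion term dominates and the composite "
      "score is unfavourable)")
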