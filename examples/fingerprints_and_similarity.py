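"""Morgan fingerprints from SMILES, and pairwise Tanimoto similarity.

Builds 1024-bit radius-2 Morgan fingerprints for a handful of molecules and
prints the nearest-neighbor similarity of each: the single number the
outlier filter later thresholds.
"""

import chemclust as cc

molecules = [
    cc.MoleculeRecord("ethanol", "CCO"),
    cc.MoleculeRecord("propanol", "CCCO"),
    cc.MoleculeRecord("butanol", "CCCCO"),
    cc.MoleculeRecord("benzene", "c1ccccc1"),
    cc.MoleculeRecord("toluene", "Cc1ccccc1"),
    cc.MoleculeRecord("caffeine", "CN1C=NC2=C1C(=O)N(C)C(=O)N2C"),
]

fps = cc.compute_fingerprints(molecules, radius=2, n_bits=1024)
profile = cc.nearest_neighbor_profile(fps)

print(f"{fps.n} molecules, {fps.n_bits}-bit fingerprints")
print(f"{'molecule':<10} {'closest':<10} tanimoto")
for mol_id, nn_id, s in zip(profile.ids, profile.nn_id, profile.nn_sim):
    print(f"{mol_id:<10} {nn_id:<10} {s:.3f}")
print(
    "\nEach row gives the molecule's single most similar companion; a low value\n"
    "means the molecule is structurally isolated in this set (an outlier candidate)."
)
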