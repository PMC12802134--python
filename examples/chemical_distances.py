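"""Compute chemical distances between metabolites and embed them.

Builds Morgan (2048-bit) and MQN (42-count) fingerprints for a few named
small molecules, derives Tanimoto and city-block distance matrices, and
embeds the Tanimoto distances into Euclidean coordinates with PCoA.
"""

from mmrules.chem import MetaboliteID, build_metabolite_distances
from mmrules.geometry import pcoa, select_dims_metab

molecules = [
    MetaboliteID("ethanol", "SMILES", "CCO"),
    MetaboliteID("acetate", "SMILES", "CC(=O)O"),
    MetaboliteID("butyrate", "SMILES", "CCCC(=O)O"),
    MetaboliteID("glucose", "InChI",
                 "InChI=1S/C6H12O6/c7-1-2-3(8)4(9)5(10)6(11)12-2/h2-11H,1H2"),
    MetaboliteID("tryptophan", "SMILES", "C1=CC=C2C(=C1)C(=CN2)CC(C(=O)O)N"),
]

for method in ("morgan", "mqn"):
    D, unresolved = build_metabolite_distances(molecules, method)
    print(f"{method} distance matrix ({len(D.labels)} metabolites):")
    for i, lab in enumerate(D.labels):
        row = "  ".join(f"{D.D[i, j]:6.2f}" for j in range(len(D.labels)))
        print(f"  {lab:>11}  {row}")
    print()

D, _ = build_metabolite_distances(molecules, "morgan")
dims = select_dims_metab(D)  # components explaining 95% of variance
emb = pcoa(D, dims)
print(f"PCoA embedding: {emb.n} metabolites in {emb.dim} dimensions")
print("(short-chain fatty acids acetate/butyrate sit closer to each other",
      "than to glucose or tryptophan)")
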