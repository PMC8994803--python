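"""Fingerprint a few molecules and inspect the substructure-key block.

Shows the three topological fingerprint families, the SMARTS chemotype
counts for an aromatic amine and a phenol, and the concatenated APC_Sub
matrix the classifiers train on.
"""

import tposcreen as tp

smiles = ["Nc1ccccc1", "Oc1ccc(Cl)cc1", "CSc1ccccc1", "CCCCCC"]
ids = ["aniline", "chlorophenol", "thioanisole", "hexane"]

for kind in ("rdkit_path", "morgan", "atom_pair_count"):
    vec = tp.topological_fp(smiles[0], kind)
    print(f"{kind:16s} width={vec.size}  nonzero slots={int((vec > 0).sum())}")

library = tp.SmartsLibrary.default()
counts = tp.substructure_matrix(ids, smiles, library).to_dataframe()
hit_cols = counts.columns[(counts > 0).any()]
print("\nsubstructure-key counts (nonzero keys only):")
print(counts[hit_cols].to_string())

topo = tp.topological_matrix(ids, smiles, "atom_pair_count")
both = tp.concat_fp(topo, tp.substructure_matrix(ids, smiles, library))
print(f"\nconcatenated feature set {both.feature_set_id}: "
      f"{both.shape[0]} compounds x {both.shape[1]} features "
      f"({topo.shape[1]} topological + {len(library)} keys)")
# Each key column keeps its name (sub:phenol, ...) so any downstream
# coefficient or frequency can be traced back to a named alert.
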