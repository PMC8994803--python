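"""Find structural alerts by class-conditional substructure frequency.

Generates a synthetic library, counts chemotype matches per compound, and
computes the frequency statistic (f_x * C) / (f * C_x) for the most active
group (A1) and the inactive group (C).  A key is flagged an active
substructure when freq_A1 > 1.2 and freq_A1 / freq_C > 1.2.
"""

import tposcreen as tp

spec = tp.SyntheticSpec(n_compounds=500, seed=11)
activity, truth = tp.generate_library(spec)

library = tp.SmartsLibrary.default()
counts = tp.substructure_matrix(list(activity["id"]), list(activity["smiles"]), library)
groups = dict(zip(truth["id"], truth["quaternary"]))

table = tp.frequency_table(counts, groups, counting="presence")
ranked = tp.identify_active_substructures(table, group_hi="A1", group_lo="C")
cols = ["f", "f_A1", "f_C", "freq_A1", "freq_C", "ratio", "active"]
print(ranked.loc[ranked["f"] > 0, cols].round(3).to_string())

oracle = tp.expected_frequency(truth)
print("\ntruth-based oracle ratio for the planted amine:",
      round(float(oracle.loc["primary_aromatic_amine", "ratio"]), 3))
# The planted aromatic amine tops the ranking: it is ~16x more prevalent in
# A1 than in C, so its A1/C frequency ratio dwarfs the other motifs'.  The
# SMARTS-based table and the truth-based oracle agree exactly because the
# bundled patterns define exactly the planted chemistry.
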