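"""Curate a raw dose-response table: desalt, deduplicate, convert, label.

Builds a six-row activity CSV in memory, runs the curation pipeline, and
prints the curated table.  Watch the aniline hydrochloride lose its
counter-ion, the ethanol/ethylamine mixture get rejected, the duplicate
collapse, and the AC50 of 5 uM on a partial curve (bottom plateau 20 %)
convert to an IC50 of about 2.63 uM via the Hill factor
((20-50)/(50-100))^(1/1) = 0.6.
"""

import tempfile
from pathlib import Path

import tposcreen as tp

RAW = """\
id,name,smiles,max_inhibition,a,b,c,ac50
1,aniline HCl,Nc1ccccc1.Cl,80,20,100,1,5
2,aniline,Nc1ccccc1,80,20,100,1,5
3,phenol,Oc1ccccc1,35,,,,
4,mixture,CCO.CCN,10,,,,
5,toluene,Cc1ccccc1,5,,,,
6,resorcinol,Oc1cccc(O)c1,90,8,100,1.2,1.5
"""

with tempfile.TemporaryDirectory() as tmp:
    path = Path(tmp) / "raw.csv"
    path.write_text(RAW)
    curated, log = tp.curate_table(path)

print(curated[["id", "smiles", "max_inhibition", "ic50", "binary", "ternary", "quaternary"]]
      .to_string(index=False))
print()
print(log.summary())
# The quaternary label splits strong inhibitors at 10 uM: both converted
# IC50s land below 10, so rows 1 and 6 are A1 (most active); the 35 %
# inhibitor is B; weak rows are C.
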