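# Substructure-key chemotype library: structural-alert families relevant to
# thyroid peroxidase inhibition.  Columns: key_name <TAB> SMARTS <TAB> mode
# (mode: presence -> 0/1 key; occurrence -> number of distinct matches).
# Users may substitute any library in this format (e.g. the official ToxPrint
# chemotype definitions exported as SMARTS).
primary_aromatic_amine	[NX3;H2][c]	occurrence
secondary_aromatic_amine	[NX3;H1]([#6])[c]	occurrence
phenol	[OX2H][c]	occurrence
enol_ether	[CX3]=[CX3][OX2][#6]	occurrence
thioenol_ether	[CX3]=[CX3][SX2][#6]	occurrence
thioether	[#6][SX2][#6]	occurrence
carbothioic_s_ester	[CX3](=[OX1])[SX2][#6]	occurrence
thiocyanate	[SX2][CX2]#[NX1]	occurrence
sulfenic_derivative	[#6][SX2][OX2]	occurrence
carbodithioic_ester	[CX3](=[SX1])[SX2][#6]	occurrence
heterocyclic_nitrogen	[nR]	occurrence
heterocyclic_sulfur	[sR]	occurrence
vinylogous_carbonyl	[CX3]=[CX3][CX3]=[OX1]	occurrence
phosphate_ester	[PX4](=[OX1])([OX2])[OX2]	occurrence
disulfide	[#6][SX2][SX2][#6]	occurrence
quinone	O=C1C=CC(=O)C=C1	occurrence
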