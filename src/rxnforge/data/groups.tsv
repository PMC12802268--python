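# name	smarts	origin_atom_position (0-based)
amine1	[NX3;H2;+0;!$(N[!#6;!#1]);!$(NC=O)]	0
amine2	[NX3;H1;+0;!$(N[!#6;!#1]);!$(NC=O)]	0
amine3	[NX3;H0;+0;!$(N[!#6;!#1]);!$(NC=O)]	0
carboxylic_acid	[CX3](=[OX1])[OX2H1]	0
boronic_acid	[BX3]([OX2H])[OX2H]	0
sulfonamide	[SX4](=[OX1])(=[OX1])[NX3]	0
azide	[NX2]=[NX2+]=[NX1-]	0
terminal_alkyne	[CX2]#[CX2H1]	0
aryl_iodide	[c][I]	0
aryl_bromide	[c][Br]	0
aryl_chloride	[c][Cl]	0
aryl_fluoride	[c][F]	0
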