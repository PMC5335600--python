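# SYNTHETIC stand-in coefficient table for the hybrid fragmental log P
# predictor (27 SMARTS fragments + 7 topological descriptor terms).
# These coefficients were chosen by the package authors to be directionally
# sensible (hydrophobic fragments positive, polar fragments negative); they
# are NOT the coefficients of any published fragmental system. Supply your
# own table to reproduce a specific model.
intercept	0.215
fragment	[CX4H3]	0.472	aliphatic methyl
fragment	[CX4H2]	0.398	aliphatic methylene
fragment	[CX4H1]	0.236	aliphatic methine
fragment	[CX4H0]	0.120	quaternary carbon
fragment	[CX3]=[CX3]	0.385	olefinic carbon pair
fragment	[CX2]#[CX2]	0.120	alkyne
fragment	c	0.294	aromatic carbon
fragment	[cH0]	0.080	substituted aromatic carbon
fragment	[F]	0.210	fluorine
fragment	[Cl]	0.650	chlorine
fragment	[Br]	0.850	bromine
fragment	[I]	1.050	iodine
fragment	[OX2H]	-1.120	hydroxyl
fragment	[OX2H0;!$(O=*)]	-0.470	ether oxygen
fragment	[CX3]=[OX1]	-0.650	carbonyl
fragment	[CX3](=O)[OX2H1]	-0.420	carboxylic acid
fragment	[CX3](=O)[OX2H0]	-0.330	ester
fragment	[NX3;H2]	-1.250	primary amine
fragment	[NX3;H1]	-0.910	secondary amine
fragment	[NX3;H0;!$(N=*);!a]	-0.620	tertiary amine
fragment	[NX3][CX3]=[OX1]	-0.520	amide nitrogen
fragment	[n]	-0.480	aromatic nitrogen
fragment	[$([NX3](=O)=O),$([NX3+](=O)[O-])]	-0.180	nitro group
fragment	[NX1]#[CX2]	-0.340	nitrile
fragment	[SX2]	0.410	divalent sulfur
fragment	[$([#16X4](=[OX1])=[OX1])]	-1.150	sulfonyl
fragment	[PX4]	-0.700	phosphorus(V)
descriptor	ring_count	0.062
descriptor	rotatable_bonds	-0.021
descriptor	heavy_atoms	0.008
descriptor	aromatic_ring_count	0.055
descriptor	heteroatoms	-0.045
descriptor	hbd	-0.080
descriptor	hba	-0.050
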