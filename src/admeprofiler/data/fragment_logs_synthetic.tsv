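# SYNTHETIC stand-in coefficient table for the 16-fragment solubility
# predictor (fragment-count sum modulated by sqrt(MW)).
# Coefficients chosen by the package authors to be directionally sensible
# (polar fragments raise log S, hydrophobic/aromatic fragments lower it);
# they are NOT the coefficients of any published fragmental system.
intercept	-1.10
fragment	[CX4H3]	-1.80	aliphatic methyl
fragment	[CX4H2]	-1.55	aliphatic methylene
fragment	[CX4H1]	-1.20	aliphatic methine
fragment	c	-1.95	aromatic carbon
fragment	[OX2H]	3.80	hydroxyl
fragment	[OX2H0;!$(O=*)]	1.60	ether oxygen
fragment	[CX3]=[OX1]	2.30	carbonyl
fragment	[CX3](=O)[OX2H1]	3.10	carboxylic acid
fragment	[NX3;H2,H1;!$(NC=O)]	3.40	primary/secondary amine
fragment	[NX3;H0;!$(N=*);!a]	1.90	tertiary amine
fragment	[n]	1.70	aromatic nitrogen
fragment	[NX3][CX3]=[OX1]	2.60	amide
fragment	[F,Cl,Br,I]	-1.40	halogen
fragment	[SX2]	-1.30	divalent sulfur
fragment	[$([#16X4](=[OX1])=[OX1])]	2.90	sulfonyl
fragment	[$([NX3](=O)=O),$([NX3+](=O)[O-])]	0.90	nitro group
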