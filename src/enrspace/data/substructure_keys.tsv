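# Functional-group substructure count keys: name<TAB>SMARTS<TAB>positive example SMILES
alkane_carbon	[CX4]	CC
methyl	[CH3]	CC
methylene	[CH2]	CCC
quaternary_carbon	[CX4H0]([#6])([#6])([#6])[#6]	CC(C)(C)C
alkene	[CX3]=[CX3]	C=C
alkyne	[CX2]#[CX2]	C#C
aromatic_carbon	c	c1ccccc1
aromatic_nitrogen	n	c1ccncc1
aromatic_oxygen	o	c1ccoc1
aromatic_sulfur	s	c1ccsc1
benzene_ring	c1ccccc1	Cc1ccccc1
halogen	[F,Cl,Br,I]	CCl
fluoro	[F]	CF
chloro	[Cl]	CCl
bromo	[Br]	CBr
iodo	[I]	CI
trifluoromethyl	[CX4]([F])([F])[F]	FC(F)(F)c1ccccc1
alkyl_halide	[CX4][F,Cl,Br,I]	CCCl
aryl_halide	c[F,Cl,Br,I]	Clc1ccccc1
vinyl_halide	[CX3]=[CX3][F,Cl,Br,I]	ClC=C
alcohol	[OX2H][CX4]	CCO
phenol	[OX2H]c	Oc1ccccc1
ether	[OD2]([#6])[#6]	COC
aryl_ether	[OX2](c)[#6]	COc1ccccc1
peroxide	[OX2][OX2]	CCOOCC
epoxide	[OX2r3]1[#6r3][#6r3]1	CC1CO1
carbonyl	[CX3]=[OX1]	CC(C)=O
aldehyde	[CX3H1](=O)[#6]	CC=O
ketone	[#6][CX3](=O)[#6]	CC(C)=O
carboxylic_acid	[CX3](=O)[OX2H1]	CC(=O)O
carboxylate_ester	[#6][CX3](=O)[OX2H0][#6]	CC(=O)OC
acyl_halide	[CX3](=[OX1])[F,Cl,Br,I]	CC(=O)Cl
anhydride	[CX3](=[OX1])[OX2][CX3](=[OX1])	CC(=O)OC(C)=O
acetal	[CX4]([OX2])[OX2]	COC(C)OC
enol_ether	[OX2][CX3]=[CX3]	COC=C
michael_acceptor	[CX3]=[CX3][CX3]=[OX1]	CC(=O)C=C
primary_amine	[NX3;H2;!$(NC=O)][#6]	CCN
secondary_amine	[NX3;H1;!$(NC=O)]([#6])[#6]	CNC
tertiary_amine	[NX3;H0;!$(NC=O);!$(N=O)]([#6])([#6])[#6]	CN(C)C
aniline	[NX3;!$([NX3]=O);!$([NX3+])]c	Nc1ccccc1
quaternary_ammonium	[NX4+]	C[N+](C)(C)C
amide	[NX3][CX3](=[OX1])	CC(=O)NC
urea	[NX3][CX3](=[OX1])[NX3]	NC(=O)N
carbamate	[NX3][CX3](=[OX1])[OX2]	COC(=O)NC
guanidine	[NX3][CX3](=[NX2])[NX3]	NC(=N)N
amidine	[NX3][CX3]=[NX2]	CC(=N)N
nitrile	[NX1]#[CX2]	CC#N
nitro	[$([NX3](=O)=O),$([NX3+](=O)[O-])]	O=[N+]([O-])c1ccccc1
nitroso	[NX2]=[OX1]	O=Nc1ccccc1
n_oxide	[$([#7X4+][OX1-]),$([#7v5]=[OX1]);!$([#7](~[O])~[O])]	C[N+](C)(C)[O-]
azo	[#6][NX2]=[NX2][#6]	c1ccccc1N=Nc1ccccc1
azide	[NX2]=[NX2+]=[NX1-]	CCN=[N+]=[N-]
hydrazine	[NX3][NX3]	NNc1ccccc1
hydrazone	[NX3][NX2]=[CX3]	CC=NN
imine	[CX3]=[NX2]	CC=NC
oxime	[CX3]=[NX2][OX2H]	CC=NO
hydroxylamine	[NX3][OX2H]	CNO
o_n_single_bond	[#7][OX2]	CON
isocyanate	[NX2]=[CX2]=[OX1]	CN=C=O
thiol	[SX2H]	CCS
thioether	[SX2]([#6])[#6]	CSC
disulfide	[SX2][SX2]	CSSC
sulfoxide	[#16X3](=[OX1])([#6])[#6]	CS(=O)C
sulfone	[#16X4](=[OX1])(=[OX1])([#6])[#6]	CS(=O)(=O)C
sulfonamide	[#16X4](=[OX1])(=[OX1])[NX3]	CS(=O)(=O)N
sulfonic_acid	[#16X4](=[OX1])(=[OX1])[OX2H]	CS(=O)(=O)O
sulfonate_ester	[#16X4](=[OX1])(=[OX1])[OX2][#6]	CS(=O)(=O)OC
thiocarbonyl	[CX3]=[SX1]	NC(=S)N
thiourea	[NX3][CX3](=[SX1])[NX3]	NC(=S)N
phosphorus	[#15]	COP(=O)(OC)OC
boron	[#5]	OB(O)c1ccccc1
silicon	[#14]	C[Si](C)(C)C
pyridine_ring	c1ccncc1	c1ccncc1
pyrimidine_ring	c1cncnc1	c1cncnc1
pyrazine_ring	c1cnccn1	c1cnccn1
pyridazine_ring	c1ccnnc1	c1ccnnc1
pyrrole_ring	c1cc[nH]c1	c1cc[nH]c1
furan_ring	c1ccoc1	c1ccoc1
thiophene_ring	c1ccsc1	c1ccsc1
imidazole_ring	c1cnc[nH]1	c1cnc[nH]1
pyrazole_ring	c1cc[nH]n1	c1cc[nH]n1
oxazole_ring	c1ocnc1	c1ocnc1
thiazole_ring	c1scnc1	c1scnc1
naphthalene	c1ccc2ccccc2c1	c1ccc2ccccc2c1
quinoline	c1ccc2ncccc2c1	c1ccc2ncccc2c1
indole	c1ccc2[nH]ccc2c1	c1ccc2[nH]ccc2c1
biphenyl	c1ccccc1-c1ccccc1	c1ccccc1-c1ccccc1
diaryl_ether	c[OX2]c	c1ccccc1Oc1ccccc1
benzylic_carbon	[CX4H2]c	Cc1ccccc1CC
cyclopropyl	[CX4r3]1[CX4r3][CX4r3]1	C1CC1
cyclohexyl	C1CCCCC1	C1CCCCC1
pyrrolidine_ring	C1CCNC1	C1CCNC1
piperidine_ring	C1CCNCC1	C1CCNCC1
piperazine_ring	C1CNCCN1	C1CNCCN1
morpholine_ring	C1COCCN1	C1COCCN1
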