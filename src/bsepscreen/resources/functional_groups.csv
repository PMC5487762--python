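# Functional-group SMARTS catalog (Daylight-style patterns), version 1.
# Columns: name, smarts. Lines starting with '#' are comments.
name,smarts
alkyl_carbon,[CX4]
vinyl_carbon,[$([CX3]=[CX3])]
allenic_carbon,[$([CX2](=C)=C)]
acetylenic_carbon,[$([CX2]#C)]
arene,c
aromatic_nitrogen,n
carbonyl,[CX3]=[OX1]
carbonyl_with_carbon,[CX3](=[OX1])C
carbonyl_with_nitrogen,[OX1]=[CX3][#7]
carbonyl_with_oxygen,[CX3](=[OX1])[OX2]
aldehyde,[CX3H1](=O)[#6]
ketone,[#6][CX3](=O)[#6]
thioester,S([#6])[CX3](=O)[#6]
carboxylic_acid,[CX3](=O)[OX2H1]
carboxylate_ion,[CX3](=O)[O-]
ester,[#6][CX3](=O)[OX2H0][#6]
carbamate,[NX3][CX3](=[OX1])[OX2H0]
carbamic_acid,[NX3][CX3](=[OX1])[OX2H1]
amide,[NX3][CX3]=[OX1]
primary_amide,[CX3](=[OX1])[NX3H2]
secondary_amide,[CX3](=[OX1])[NX3H1][#6]
tertiary_amide,[CX3](=[OX1])[NX3H0]([#6])[#6]
cyanamide,[NX3][CX2]#[NX1]
primary_amine,[NX3H2;!$(NC=O)][#6]
secondary_amine,[NX3H1;!$(NC=O)]([#6])[#6]
tertiary_amine,[NX3H0;!$(NC=O);!$(N=O)]([#6])([#6])[#6]
quaternary_nitrogen,[NX4+]
enamine,[NX3][CX3]=[CX3]
imine,[CX3]=[NX2]
iminium,[NX3+]=[CX3]
nitrile,[NX1]#[CX2]
isonitrile,[CX1-]#[NX2+]
nitro_group,"[$([NX3](=O)=O),$([NX3+](=O)[O-])][!#8]"
nitroso,[NX2]=[OX1]
n_oxide,"[$([#7+][OX1-]),$([#7v5]=[OX1]);!$([#7](~[O])~[O])]"
azo,[#6][NX2]=[NX2][#6]
azide,"[$([NX1]~[NX2]~[NX3,NX2])]"
diazonium,[#6][NX2+]#[NX1]
hydrazine,[NX3][NX3]
hydrazone,[NX3][NX2]=[CX3]
hydroxylamine,[NX3][OX2H1]
hydroxyl,[OX2H]
alcohol,[OX2H][CX4]
phenol,[OX2H][cX3]
enol,[OX2H][#6X3]=[#6]
ether,[OD2]([#6])[#6]
alkoxy,[OX2H0][CX4]
aromatic_ether,[OX2H0](c)[#6]
peroxide,[OX2][OX2]
acetal,[CX4]([OX2H0])([OX2H0])
hemiacetal,[CX4]([OX2H1])([OX2H0])
thiol,[SX2H]
thioether,[SX2H0]([#6])[#6]
disulfide,[SX2][SX2]
sulfoxide,"[$([SX3](=[OX1])([#6])[#6]),$([SX3+]([OX1-])([#6])[#6])]"
sulfone,[SX4](=[OX1])(=[OX1])([#6])[#6]
sulfonamide,[SX4](=[OX1])(=[OX1])([!#8])[NX3]
sulfonic_acid,[SX4](=[OX1])(=[OX1])([#6])[OX2H]
sulfonate_ester,[SX4](=[OX1])(=[OX1])([#6])[OX2H0][#6]
thiocarbonyl,[#6X3]=[SX1]
thioamide,[NX3][CX3]=[SX1]
halide,"[F,Cl,Br,I]"
fluoride,[F]
chloride,[Cl]
bromide,[Br]
iodide,[I]
trifluoromethyl,[CX4](F)(F)F
acyl_halide,"[CX3](=[OX1])[F,Cl,Br,I]"
phosphate,[PX4](=[OX1])([OX2])([OX2])[OX2]
phosphonic_acid,[PX4](=[OX1])([OX2H])([OX2H])[#6]
guanidine,[NX3][CX3](=[NX2])[NX3]
amidine,[NX3][CX3]=[NX2]
urea,[NX3][CX3](=[OX1])[NX3]
thiourea,[NX3][CX3](=[SX1])[NX3]
isocyanate,[NX2]=[CX2]=[OX1]
isothiocyanate,[NX2]=[CX2]=[SX1]
epoxide,[OX2r3]1[#6r3][#6r3]1
lactone,[CX3](=[OX1])[OX2H0][#6r]
lactam,[NX3R][CX3R]=[OX1]
aniline,[NX3;!$(NC=O)]c
pyridine_like_nitrogen,[nX2]
pyrrole_like_nitrogen,[nX3H1]
imidazole,c1cnc[nH]1
oxazole,c1ocnc1
thiazole,c1scnc1
furan,c1ccoc1
thiophene,c1ccsc1
boronic_acid,[BX3]([OX2H])[OX2H]
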