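CCO	ethanol
CC(C)CCO	isoamyl_alcohol_core
CCCCO	1-butanol
CCCCCCCCO	1-octanol
CCCCCCO	1-hexanol
CC(=O)OCC	ethyl_acetate
CCCC(=O)OCC	ethyl_butanoate
CCCCCC(=O)OCC	ethyl_hexanoate
CCCCCCCC(=O)OCC	ethyl_octanoate
CCCCCCCCCC(=O)OCC	ethyl_decanoate
CCCCCCCCC(=O)OC	methyl_nonanoate
CCCCCCCCCC(=O)OC	methyl_decanoate
CC(=O)OCC(C)C	isobutyl_acetate
CC(=O)OCCC(C)C	isoamyl_acetate
CC(=O)O	acetic_acid
CCCC(=O)O	butanoic_acid
CCCCCC(=O)O	hexanoic_acid
CCCCCCC(=O)O	heptanoic_acid
CCCCCCCC(=O)O	octanoic_acid
CCCCCCCCCC(=O)O	decanoic_acid
CCCCCCCCCCCC(=O)O	dodecanoic_acid
CCCCCC=O	hexanal
CCCCCCCC=O	octanal
CCCCCCCCC=O	nonanal
CC=O	acetaldehyde
CCC(=O)C	2-butanone
CC(=O)C(C)O	acetoin
CC(=O)C(C)=O	diacetyl
Oc1ccccc1	phenol
Cc1ccc(O)cc1	p-cresol
COc1ccccc1O	guaiacol
COc1ccc(C)cc1O	4-methylguaiacol
CCc1ccc(O)cc1	4-ethylphenol
CCc1ccc(O)c(OC)c1	4-ethylguaiacol
COc1cc(C=O)ccc1O	vanillin
COc1cc(CC=C)ccc1O	eugenol
CC1CCC(C(C)C)C(O)C1	menthol
CC(C)=CCCC(C)CCO	citronellol
CC(C)=CCCC(C)=CCO	geraniol
CC(C)=CCCC(C)(O)C=C	linalool
CC1=CCC(CC1)C(C)=C	limonene
CC1=CCC2CC1C2(C)C	alpha-pinene
CC(C)C1CCC(C)CC1O	menthol_isomer
O=C1CCCO1	gamma-butyrolactone
CCCCC1CCC(=O)O1	gamma-nonalactone_core
CCCCCC1CCC(=O)O1	gamma-decalactone_core
CCCCCCC1CCC(=O)O1	whisky_lactone_core
CC1CCC(=O)O1	gamma-valerolactone
O=Cc1ccco1	furfural
Cc1ccc(C=O)o1	5-methylfurfural
OCC1CCCO1	tetrahydrofurfuryl_alcohol
CSC	dimethyl_sulfide
CCCCCCCCC(=O)OCC	ethyl_nonanoate
Oc1ccc(Cl)cc1OC	4-chloroguaiacol
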