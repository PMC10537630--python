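# Default genotoxicity-relevant chemotype set: name<TAB>SMARTS.
# Generic structural-alert substructures standing in the role of a
# proprietary chemotype library; users may load any two-column file of
# the same layout.
nitroso	[NX2]=O
nitrosamine	[NX3][NX2]=O
nitro_aromatic	[c][N+](=O)[O-]
carbamate	[NX3][CX3](=O)[OX2]
sulfonic_ester_alkyl	[CX4][OX2][SX4](=[OX1])(=[OX1])
epoxide	C1OC1
aziridine	C1CN1
quinone	O=C1C=CC(=O)C=C1
alkyl_chloride	[CX4][Cl]
alkyl_bromide	[CX4][Br]
alkyl_iodide	[CX4][I]
michael_acceptor_enone	C=CC(=O)[#6]
aldehyde	[CX3H1](=O)[#6]
hydrazine	[NX3][NX3]
azo	[#6]N=N[#6]
aromatic_amine	[NX3;H2,H1][c]
aromatic_azide	[c]N=[N+]=[N-]
pah_naphthalene	c1ccc2ccccc2c1
pah_phenanthrene	c1ccc2ccc3ccccc3c2c1
steroid_gonane	C1CC2CCC3C(CCC4CCCC34)C2C1
phenol	[OX2H][c]
aryl_ether	[c][OX2][CX4]
halogenated_aromatic	[c][Cl,Br,I]
beta_haloethylamine	[NX3][CX4][CX4][Cl,Br]
thiophosphate	[PX4]=[SX1]
organophosphate	[OX2][PX4](=[OX1])
isocyanate	[NX2]=C=O
acyl_halide	[CX3](=O)[Cl,Br]
urea_fragment	[NX3][CX3](=O)[NX3]
thiourea_fragment	[NX3][CX3](=S)[NX3]
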