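smiles,label,endpoint,cas,name,source,compliant
CCO,1,mn_in_vitro,64-17-5,ethanol,demo,true
CC(=O)[O-].[Na+],0,mn_in_vitro,127-09-3,sodium acetate,demo,true
C1CCCCC1N.Cl,1,mn_in_vitro,,cyclohexylamine hydrochloride,demo,
CCO.OCC,1,mn_in_vitro,,ethanol-ethanol mixture,demo,
C[Sn](C)(C)C,1,mn_in_vitro,594-27-4,tetramethyltin,demo,
Oc1ccccc1,1,mn_in_vitro,108-95-2,phenol,demo,false
c1ccccc1O,0,mn_in_vitro,108-95-2,phenol repeat,demo,true
CCN,1,mn_in_vitro,75-04-7,ethylamine,demo,
NCC,1,mn_in_vitro,75-04-7,ethylamine repeat,demo,
c1ccncc1,0,mn_in_vitro,110-86-1,pyridine,demo,true
CC(=O)Nc1ccc(O)cc1,0,mn_in_vitro,103-90-2,paracetamol,demo,true
ClCCCl,1,mn_in_vitro,107-06-2,"1,2-dichloroethane",demo,true
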