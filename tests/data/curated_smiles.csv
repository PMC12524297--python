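id,smiles,label
benzene,c1ccccc1,1
toluene,Cc1ccccc1,1
phenol,Oc1ccccc1,1
aniline,Nc1ccccc1,1
nitrobenzene,O=[N+]([O-])c1ccccc1,1
chloroform,ClC(Cl)Cl,1
carbon_tetrachloride,ClC(Cl)(Cl)Cl,1
dichloromethane,ClCCl,1
formaldehyde,C=O,1
acetonitrile,CC#N,1
glucose,OC[C@H]1OC(O)[C@H](O)[C@@H](O)[C@@H]1O,0
sucrose,OC[C@H]1O[C@@](CO)(O[C@H]2O[C@H](CO)[C@@H](O)[C@H](O)[C@H]2O)[C@@H](O)[C@@H]1O,0
glycerol,OCC(O)CO,0
citric_acid,OC(=O)CC(O)(CC(O)=O)C(O)=O,0
ascorbic_acid,OC[C@H](O)[C@H]1OC(=O)C(O)=C1O,0
glycine,NCC(O)=O,0
alanine,C[C@H](N)C(O)=O,0
leucine,CC(C)C[C@H](N)C(O)=O,0
lysine,NCCCC[C@H](N)C(O)=O,0
lactic_acid,CC(O)C(O)=O,0
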