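carboxylic_acid_0001	CCCc1cc(CC(C)C)cc(C(=O)O)c1
carboxylic_acid_0002	CCOc1ccc(C(=O)O)cc1C(C)C
carboxylic_acid_0003	CCCc1cc(CC(=O)O)cc(C(C)C)c1
carboxylic_acid_0004	COc1cc(OC)cc(C(=O)O)c1
carboxylic_acid_0005	Cc1cc(C(=O)O)cc(C(F)(F)F)c1
carboxylic_acid_0006	CCOc1cc(CO)cc(CC(=O)O)c1
carboxylic_acid_0007	CCOc1cc(CC)cc(CC(=O)O)c1
carboxylic_acid_0008	COc1cc(F)cc(C(=O)O)c1
carboxylic_acid_0009	CCOc1cc(C(=O)O)ccc1OC
carboxylic_acid_0010	CCCc1cc(CO)cc(C(=O)O)c1
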