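boronic_acid_0001	CCCc1cc(CC(C)C)cc(B(O)O)c1
boronic_acid_0002	CCOc1ccc(B(O)O)cc1C(C)C
boronic_acid_0003	CCCc1ccc(C(C)C)c(B(O)O)c1
boronic_acid_0004	COc1cc(OC)cc(B(O)O)c1
boronic_acid_0005	Cc1cc(B(O)O)cc(C(F)(F)F)c1
boronic_acid_0006	CCOc1ccc(CO)cc1B(O)O
boronic_acid_0007	CCOc1ccc(CC)cc1B(O)O
boronic_acid_0008	COc1cc(F)cc(B(O)O)c1
boronic_acid_0009	CCOc1cc(B(O)O)ccc1OC
boronic_acid_0010	CCCc1cc(CO)cc(B(O)O)c1
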