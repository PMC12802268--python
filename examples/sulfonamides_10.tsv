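sulfonamide_0001	CCCc1cc(CC(C)C)cc(S(N)(=O)=O)c1
sulfonamide_0002	CCOc1ccc(S(N)(=O)=O)cc1C(C)C
sulfonamide_0003	CCCc1cc(CS(N)(=O)=O)cc(C(C)C)c1
sulfonamide_0004	COc1cc(OC)cc(S(N)(=O)=O)c1
sulfonamide_0005	Cc1cc(C(F)(F)F)cc(S(N)(=O)=O)c1
sulfonamide_0006	CCOc1cc(CO)cc(CS(N)(=O)=O)c1
sulfonamide_0007	CCOc1cc(CC)cc(CS(N)(=O)=O)c1
sulfonamide_0008	COc1cc(F)cc(S(N)(=O)=O)c1
sulfonamide_0009	CCOc1cc(S(N)(=O)=O)ccc1OC
sulfonamide_0010	CCCc1cc(CO)cc(S(N)(=O)=O)c1
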