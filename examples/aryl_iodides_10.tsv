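aryl_iodide_0001	CCCc1cc(I)cc(CC(C)C)c1
aryl_iodide_0002	CCOc1ccc(I)cc1C(C)C
aryl_iodide_0003	CCCc1ccc(C(C)C)c(I)c1
aryl_iodide_0004	COc1cc(I)cc(OC)c1
aryl_iodide_0005	Cc1cc(I)cc(C(F)(F)F)c1
aryl_iodide_0006	CCOc1ccc(CO)cc1I
aryl_iodide_0007	CCOc1ccc(CC)cc1I
aryl_iodide_0008	COc1cc(F)cc(I)c1
aryl_iodide_0009	CCOc1cc(I)ccc1OC
aryl_iodide_0010	CCCc1cc(I)cc(CO)c1
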