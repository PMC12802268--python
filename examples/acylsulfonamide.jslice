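{
  "id": "TOY-7009",
  "name": "Acylsulfonamide from sulfonamide and carboxylic acid, toy scale",
  "version": "1",
  "history": [
    [
      "2025-01-01T00:00:00",
      "initial toy encoding"
    ]
  ],
  "references": [],
  "comments": "",
  "conditions": "EDC, DMAP, DCM, rt",
  "metrics": {
    "yield": 70
  },
  "smirks": "[SX4:1](=[O:2])(=[O:3])[NX3;H2:4].[CX3:5](=[O:6])[OX2H1:7]>>[SX4:1](=[O:2])(=[O:3])[NX3;H1:4][CX3:5]=[O:6]",
  "reactant_smarts": [
    "[SX4:1](=[O:2])(=[O:3])[NX3;H2:4]",
    "[CX3:5](=[O:6])[OX2H1:7]"
  ],
  "product_smarts": "",
  "logic": [
    "",
    "if molecule has at least 2 carboxylic_acid groups then kill"
  ],
  "ghosts": [
    "O"
  ]
}
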