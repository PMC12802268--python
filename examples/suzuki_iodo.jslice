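{
  "id": "TOY-6005",
  "name": "Suzuki-Miyaura cross-coupling (iodo), toy scale",
  "version": "1",
  "history": [
    [
      "2025-01-01T00:00:00",
      "initial toy encoding"
    ]
  ],
  "references": [],
  "comments": "",
  "conditions": "Pd(PPh3)4, K2CO3, dioxane/water, 80 C",
  "metrics": {
    "yield": 80,
    "reliability": 90
  },
  "smirks": "[c:1][I:2].[c:3][BX3]([OX2H])[OX2H]>>[c:1]-[c:3]",
  "reactant_smarts": [
    "[c:1][I:2]",
    "[c:3][BX3]([OX2H])[OX2H]"
  ],
  "product_smarts": "",
  "logic": [
    "if molecule has at least 2 iodines then kill\nforeach nitrogen atom offpath defined as n in molecule {\nif n is the origin of amine1 group then kill\n}\nforeach chlorine atom offpath defined as cl in molecule {\nif cl is chlorine atom then lower rating slightly\n}\nforeach bromine atom offpath defined as br in molecule {\nif br is bromine atom then lower rating moderately\n}",
    "if molecule has at least 1 iodine then kill\nforeach nitrogen atom offpath defined as n in molecule {\nif n is the origin of amine1 group then kill\n}"
  ],
  "ghosts": []
}
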