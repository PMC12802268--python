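<transform id="TOY-6005" name="Suzuki-Miyaura cross-coupling (iodo), toy scale" version="1">
  <description>
    <history>
      <event timestamp="2025-01-01T00:00:00">initial toy encoding</event>
    </history>
  </description>
  <metrics>
    <yield>80</yield>
    <reliability>90</reliability>
  </metrics>
  <pattern>
    <smirks>[c:1][I:2].[c:3][BX3]([OX2H])[OX2H]&gt;&gt;[c:1]-[c:3]</smirks>
    <reactant index="1">[c:1][I:2]</reactant>
    <reactant index="2">[c:3][BX3]([OX2H])[OX2H]</reactant>
  </pattern>
  <conditions>Pd(PPh3)4, K2CO3, dioxane/water, 80 C</conditions>
  <logic reactant="1">
if molecule has at least 2 iodines then kill
foreach nitrogen atom offpath defined as n in molecule {
if n is the origin of amine1 group then kill
}
foreach chlorine atom offpath defined as cl in molecule {
if cl is chlorine atom then lower rating slightly
}
foreach bromine atom offpath defined as br in molecule {
if br is bromine atom then lower rating moderately
}
</logic>
  <logic reactant="2">
if molecule has at least 1 iodine then kill
foreach nitrogen atom offpath defined as n in molecule {
if n is the origin of amine1 group then kill
}
</logic>
</transform>
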