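<transform id="TOY-7009" name="Acylsulfonamide from sulfonamide and carboxylic acid, toy scale" version="1">
  <description>
    <history>
      <event timestamp="2025-01-01T00:00:00">initial toy encoding</event>
    </history>
  </description>
  <metrics>
    <yield>70</yield>
  </metrics>
  <pattern>
    <smirks>[SX4:1](=[O:2])(=[O:3])[NX3;H2:4].[CX3:5](=[O:6])[OX2H1:7]&gt;&gt;[SX4:1](=[O:2])(=[O:3])[NX3;H1:4][CX3:5]=[O:6]</smirks>
    <reactant index="1">[SX4:1](=[O:2])(=[O:3])[NX3;H2:4]</reactant>
    <reactant index="2">[CX3:5](=[O:6])[OX2H1:7]</reactant>
  </pattern>
  <conditions>EDC, DMAP, DCM, rt</conditions>
  <logic reactant="1">

</logic>
  <logic reactant="2">
if molecule has at least 2 carboxylic_acid groups then kill
</logic>
  <ghosts>
    <ghost>O</ghost>
  </ghosts>
</transform>
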