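"""Ready-made example transforms for tests, demos, and self-checks.

Two classic couplings at toy scale:

* ``suzuki_iodo`` — aryl iodide + arylboronic acid -> biaryl, with logic
  that vetoes extra off-path iodines / off-path primary amines on the halide
  partner and down-rates off-path chlorines and bromines.
* ``acylsulfonamide`` — primary sulfonamide + carboxylic acid ->
  N-acylsulfonamide, balanced by a water ghost.
"""

from __future__ import annotations

from .logic_lang import parse_program
from .transform_model import Transform, TransformMeta, TransformMetrics

__all__ = ["suzuki_iodo", "acylsulfonamide"]

_SUZUKI_LOGIC_R1 = """\
// extra aryl iodides would cross-couple uncontrollably
if molecule has at least 2 iodines then kill
// free primary amines poison the catalyst
foreach nitrogen atom offpath defined as n in molecule {
if n is the origin of amine1 group then kill
}
// competing halides are tolerated but disfavored
foreach chlorine atom offpath defined as cl in molecule {
if cl is chlorine atom then lower rating slightly
}
foreach bromine atom offpath defined as br in molecule {
if br is bromine atom then lower rating moderately
}
"""

_SUZUKI_LOGIC_R2 = """\
if molecule has at least 1 iodine then kill
foreach nitrogen atom offpath defined as n in molecule {
if n is the origin of amine1 group then kill
}
"""


def suzuki_iodo() -> Transform:
    meta = TransformMeta(
        id="TOY-6005",
        name="Suzuki-Miyaura cross-coupling (iodo), toy scale",
        version="1",
        history=(("2025-01-01T00:00:00", "initial toy encoding"),),
        conditions="Pd(PPh3)4, K2CO3, dioxane/water, 80 C",
    )
    return Transform(
        meta=meta,
        metrics=TransformMetrics(yield_=80, reliability=90),
        smirks="[c:1][I:2].[c:3][BX3]([OX2H])[OX2H]>>[c:1]-[c:3]",
        reactant_smarts=("[c:1][I:2]", "[c:3][BX3]([OX2H])[OX2H]"),
        reactant_logic=(parse_program(_SUZUKI_LOGIC_R1),
                        parse_program(_SUZUKI_LOGIC_R2)),
    )


_ACYL_LOGIC_R2 = """\
// diacids give mixtures
if molecule has at least 2 carboxylic_acid groups then kill
"""


def acylsulfonamide() -> Transform:
    meta = TransformMeta(
        id="TOY-7009",
        name="Acylsulfonamide from sulfonamide and carboxylic acid, toy scale",
        version="1",
        history=(("2025-01-01T00:00:00", "initial toy encoding"),),
        conditions="EDC, DMAP, DCM, rt",
    )
    return Transform(
        meta=meta,
        metrics=TransformMetrics(yield_=70),
        smirks=("[SX4:1](=[O:2])(=[O:3])[NX3;H2:4]."
                "[CX3:5](=[O:6])[OX2H1:7]"
                ">>[SX4:1](=[O:2])(=[O:3])[NX3;H1:4][CX3:5]=[O:6]"),
        reactant_smarts=("[SX4:1](=[O:2])(=[O:3])[NX3;H2:4]",
                         "[CX3:5](=[O:6])[OX2H1:7]"),
        reactant_logic=(parse_program(""),
                        parse_program(_ACYL_LOGIC_R2)),
        ghost_templates=("O",),
    )
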