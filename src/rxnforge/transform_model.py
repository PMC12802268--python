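"""In-memory transform model and the `.slice` (XML) / `.jslice` (JSON)
dialects.

A transform bundles one reaction type: identity/version metadata, optional
quality metrics, an atom-mapped reaction pattern (SMIRKS), one logic program
per reactant slot, and ghost templates emitted to balance the reaction.

The element/key sets of both dialects are defined by this package (the
original authoring tool publishes no schema); both serializations are
lossless and interconvertible.  Logic is stored as text and parsed on load,
so files stay human-readable and syntax errors surface immediately with
file context.
"""

from __future__ import annotations

import json
import re
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

from rdkit import Chem
from rdkit.Chem import AllChem

from . import logic_lang
from .logic_lang import LogicError, LogicProgram
from .pattern_engine import CompiledPattern, GroupLibrary, PatternError, compile_pattern

__all__ = [
    "TransformMeta", "TransformMetrics", "Transform", "Diagnostic",
    "TransformFormatError", "TransformValidationError",
    "read_transform", "write_transform", "validate_transform",
]

METRIC_NAMES = (
    "yield_", "reliability", "reputation", "homoselectivity",
    "heteroselectivity", "orientational_selectivity", "condition_flexibility",
    "thermodynamics",
)

METRIC_BOUNDS = (0, 100)


class TransformFormatError(ValueError):
    """Malformed `.slice` / `.jslice` content."""


class TransformValidationError(ValueError):
    """A transform violating its structural invariants."""


@dataclass(frozen=True)
class TransformMeta:
    id: str
    name: str
    version: str
    history: tuple[tuple[str, str], ...] = ()   # (timestamp, note)
    references: tuple[str, ...] = ()
    comments: str = ""
    conditions: str = ""

    def with_history_event(self, timestamp: str, note: str) -> "TransformMeta":
        """History is append-only: edits go through this method."""
        return replace(self, history=self.history + ((timestamp, note),))


@dataclass(frozen=True)
class TransformMetrics:
    """Optional bounded quality scores, each in [0, 100] when present."""

    yield_: Optional[int] = None
    reliability: Optional[int] = None
    reputation: Optional[int] = None
    homoselectivity: Optional[int] = None
    heteroselectivity: Optional[int] = None
    orientational_selectivity: Optional[int] = None
    condition_flexibility: Optional[int] = None
    thermodynamics: Optional[int] = None

    def items(self):
        for name in METRIC_NAMES:
            yield name, getattr(self, name)


@dataclass
class Transform:
    meta: TransformMeta
    metrics: TransformMetrics = field(default_factory=TransformMetrics)
    smirks: str = ""
    reactant_smarts: tuple[str, ...] = ()   # keying patterns, extensions allowed
    product_smarts: str = ""
    reactant_logic: tuple[LogicProgram, ...] = ()
    ghost_templates: tuple[str, ...] = ()   # SMILES fragments

    def __eq__(self, other):
        if not isinstance(other, Transform):
            return NotImplemented
        return (self.meta, self.metrics, self.smirks, self.reactant_smarts,
                self.product_smarts, self.reactant_logic, self.ghost_templates) \
            == (other.meta, other.metrics, other.smirks, other.reactant_smarts,
                other.product_smarts, other.reactant_logic, other.ghost_templates)

    # -- derived views ----------------------------------------------------

    def slot_smarts(self) -> tuple[str, ...]:
        """Per-slot keying patterns: explicit ones, else split from SMIRKS."""
        if self.reactant_smarts:
            return self.reactant_smarts
        return tuple(split_reaction_components(self.smirks.split(">>")[0]))

    @property
    def num_slots(self) -> int:
        return len(self.slot_smarts())

    def slot_pattern(self, slot: int) -> CompiledPattern:
        smarts = self.slot_smarts()
        if not 0 <= slot < len(smarts):
            raise IndexError(f"reactant slot {slot} out of range "
                             f"(transform has {len(smarts)})")
        return compile_pattern(smarts[slot])

    def slot_logic(self, slot: int) -> LogicProgram:
        """Missing programs mean 'no constraints'."""
        if slot < len(self.reactant_logic):
            return self.reactant_logic[slot]
        return LogicProgram()


def split_reaction_components(side: str) -> list[str]:
    """Split one side of a reaction SMARTS on top-level dots."""
    parts, depth, start = [], 0, 0
    for i, c in enumerate(side):
        if c in "([":
            depth += 1
        elif c in ")]":
            depth -= 1
        elif c == "." and depth == 0:
            parts.append(side[start:i])
            start = i + 1
    parts.append(side[start:])
    out = []
    for p in parts:
        p = p.strip()
        if p.startswith("(") and p.endswith(")"):
            p = p[1:-1]
        out.append(p)
    return [p for p in out if p]


_MAP_RE = re.compile(r":(\d+)\]")


def mapped_indices(smarts: str) -> set[int]:
    return {int(m) for m in _MAP_RE.findall(smarts)}


# ---------------------------------------------------------------------------
# validation


@dataclass(frozen=True)
class Diagnostic:
    severity: str       # 'error' | 'warning'
    location: str
    message: str


def validate_transform(t: Transform,
                       group_library: Optional[GroupLibrary] = None) -> list[Diagnostic]:
    """Structural diagnostics; an empty list means the generator will accept
    the transform without further structural failure."""
    diags: list[Diagnostic] = []

    def err(loc, msg):
        diags.append(Diagnostic("error", loc, msg))

    def warn(loc, msg):
        diags.append(Diagnostic("warning", loc, msg))

    for fld in ("id", "name", "version"):
        if not getattr(t.meta, fld):
            err(f"meta.{fld}", f"mandatory property {fld!r} is empty")

    for name, value in t.metrics.items():
        if value is not None and not (METRIC_BOUNDS[0] <= value <= METRIC_BOUNDS[1]):
            err(f"metrics.{name}",
                f"metric {name.rstrip('_')}={value} outside {METRIC_BOUNDS}")

    if not t.smirks:
        err("smirks", "transform has no reaction pattern")
        return diags

    if ">>" not in t.smirks:
        err("smirks", f"reaction pattern lacks '>>': {t.smirks!r}")
        return diags

    rxn = AllChem.ReactionFromSmarts(t.smirks)
    if rxn is None:
        err("smirks", f"unparseable reaction SMARTS {t.smirks!r}")
        return diags

    reactant_side, product_side = t.smirks.split(">>")[0], t.smirks.split(">>")[-1]
    rmaps = mapped_indices(reactant_side)
    pmaps = mapped_indices(product_side)
    orphans = pmaps - rmaps
    if orphans:
        err("smirks", "product-side mapped atoms without reactant counterpart: "
            + ", ".join(str(i) for i in sorted(orphans)))

    slot_smarts = t.slot_smarts()
    if len(t.reactant_logic) > len(slot_smarts):
        err("logic", f"{len(t.reactant_logic)} logic programs for "
            f"{len(slot_smarts)} reactant slots")

    lib = group_library
    for slot, smarts in enumerate(slot_smarts):
        try:
            pattern = compile_pattern(smarts)
        except PatternError as exc:
            err(f"reactant[{slot + 1}]", str(exc))
            continue
        if slot >= len(t.reactant_logic):
            continue
        program = t.reactant_logic[slot]
        available = set(pattern.map_index_to_pattern_atom)
        missing = program.referenced_map_indices() - available
        if missing:
            err(f"logic[{slot + 1}]",
                "logic references unmapped atom(s): "
                + ", ".join(str(i) for i in sorted(missing))
                + f" (pattern maps: {sorted(available) or 'none'})")
        if lib is None:
            lib = GroupLibrary.default()
        for gname in sorted(program.referenced_groups()):
            if gname not in lib:
                warn(f"logic[{slot + 1}]",
                     f"group {gname!r} is not in the group library")

    for i, smiles in enumerate(t.ghost_templates):
        if Chem.MolFromSmiles(smiles) is None:
            err(f"ghosts[{i}]", f"unparseable ghost SMILES {smiles!r}")

    return diags


def _require_valid(t: Transform) -> None:
    errors = [d for d in validate_transform(t) if d.severity == "error"]
    if errors:
        details = "; ".join(f"{d.location}: {d.message}" for d in errors)
        raise TransformValidationError(f"invalid transform: {details}")


# ---------------------------------------------------------------------------
# JSON dialect (.jslice)


def _transform_to_dict(t: Transform) -> dict:
    metrics = {name.rstrip("_"): value for name, value in t.metrics.items()
               if value is not None}
    return {
        "id": t.meta.id,
        "name": t.meta.name,
        "version": t.meta.version,
        "history": [list(ev) for ev in t.meta.history],
        "references": list(t.meta.references),
        "comments": t.meta.comments,
        "conditions": t.meta.conditions,
        "metrics": metrics,
        "smirks": t.smirks,
        "reactant_smarts": list(t.reactant_smarts),
        "product_smarts": t.product_smarts,
        "logic": [logic_lang.serialize_program(p) for p in t.reactant_logic],
        "ghosts": list(t.ghost_templates),
    }


def _parse_logic_blocks(texts: list[str], where: str) -> tuple[LogicProgram, ...]:
    programs = []
    for i, text in enumerate(texts):
        try:
            programs.append(logic_lang.parse_program(text))
        except LogicError as exc:
            raise TransformFormatError(
                f"{where}: logic for reactant {i + 1} failed to parse: {exc}\n"
                f"  statement text: {text.strip()!r}") from exc
    return tuple(programs)


def _transform_from_dict(data: dict, where: str) -> Transform:
    if not isinstance(data, dict):
        raise TransformFormatError(f"{where}: top-level JSON value must be an object")
    missing = [k for k in ("id", "name", "version") if not data.get(k)]
    if missing:
        raise TransformFormatError(
            f"{where}: missing mandatory element(s): {', '.join(missing)}")
    metrics_raw = data.get("metrics", {})
    kwargs = {}
    for name in METRIC_NAMES:
        key = name.rstrip("_")
        if key in metrics_raw:
            kwargs[name] = int(metrics_raw[key])
    meta = TransformMeta(
        id=str(data["id"]),
        name=str(data["name"]),
        version=str(data["version"]),
        history=tuple((str(a), str(b)) for a, b in data.get("history", [])),
        references=tuple(str(r) for r in data.get("references", [])),
        comments=str(data.get("comments", "")),
        conditions=str(data.get("conditions", "")),
    )
    return Transform(
        meta=meta,
        metrics=TransformMetrics(**kwargs),
        smirks=str(data.get("smirks", "")),
        reactant_smarts=tuple(str(s) for s in data.get("reactant_smarts", [])),
        product_smarts=str(data.get("product_smarts", "")),
        reactant_logic=_parse_logic_blocks(
            [str(x) for x in data.get("logic", [])], where),
        ghost_templates=tuple(str(g) for g in data.get("ghosts", [])),
    )


# ---------------------------------------------------------------------------
# XML dialect (.slice)


def _transform_to_xml(t: Transform) -> ET.Element:
    root = ET.Element("transform",
                      {"id": t.meta.id, "name": t.meta.name,
                       "version": t.meta.version})
    desc = ET.SubElement(root, "description")
    if t.meta.comments:
        ET.SubElement(desc, "comments").text = t.meta.comments
    if t.meta.references:
        refs = ET.SubElement(desc, "references")
        for r in t.meta.references:
            ET.SubElement(refs, "reference").text = r
    if t.meta.history:
        hist = ET.SubElement(desc, "history")
        for timestamp, note in t.meta.history:
            ev = ET.SubElement(hist, "event", {"timestamp": timestamp})
            ev.text = note
    metrics = {name.rstrip("_"): v for name, v in t.metrics.items() if v is not None}
    if metrics:
        m = ET.SubElement(root, "metrics")
        for key, value in metrics.items():
            ET.SubElement(m, key).text = str(value)
    pattern = ET.SubElement(root, "pattern")
    ET.SubElement(pattern, "smirks").text = t.smirks
    for i, smarts in enumerate(t.reactant_smarts):
        ET.SubElement(pattern, "reactant", {"index": str(i + 1)}).text = smarts
    if t.product_smarts:
        ET.SubElement(pattern, "product").text = t.product_smarts
    if t.meta.conditions:
        ET.SubElement(root, "conditions").text = t.meta.conditions
    for i, program in enumerate(t.reactant_logic):
        el = ET.SubElement(root, "logic", {"reactant": str(i + 1)})
        el.text = "\n" + logic_lang.serialize_program(program) + "\n"
    if t.ghost_templates:
        ghosts = ET.SubElement(root, "ghosts")
        for g in t.ghost_templates:
            ET.SubElement(ghosts, "ghost").text = g
    return root


def _transform_from_xml(root: ET.Element, where: str) -> Transform:
    if root.tag != "transform":
        raise TransformFormatError(
            f"{where}: expected root element <transform>, got <{root.tag}>")
    data: dict = {k: root.get(k, "") for k in ("id", "name", "version")}
    desc = root.find("description")
    data["comments"] = ""
    data["references"] = []
    data["history"] = []
    if desc is not None:
        c = desc.find("comments")
        if c is not None:
            data["comments"] = c.text or ""
        refs = desc.find("references")
        if refs is not None:
            data["references"] = [(r.text or "") for r in refs.findall("reference")]
        hist = desc.find("history")
        if hist is not None:
            data["history"] = [[ev.get("timestamp", ""), ev.text or ""]
                               for ev in hist.findall("event")]
    metrics = {}
    mel = root.find("metrics")
    if mel is not None:
        for child in mel:
            try:
                metrics[child.tag] = int(child.text)
            except (TypeError, ValueError):
                raise TransformFormatError(
                    f"{where}: metric <{child.tag}> has non-integer value "
                    f"{child.text!r}") from None
    data["metrics"] = metrics
    pattern = root.find("pattern")
    if pattern is None:
        raise TransformFormatError(f"{where}: missing <pattern> element")
    smirks = pattern.find("smirks")
    data["smirks"] = (smirks.text or "").strip() if smirks is not None else ""
    reactants = sorted(pattern.findall("reactant"),
                       key=lambda el: int(el.get("index", "0")))
    data["reactant_smarts"] = [(el.text or "").strip() for el in reactants]
    product = pattern.find("product")
    data["product_smarts"] = (product.text or "").strip() if product is not None else ""
    cond = root.find("conditions")
    data["conditions"] = (cond.text or "") if cond is not None else ""
    logic_els = sorted(root.findall("logic"),
                       key=lambda el: int(el.get("reactant", "0")))
    data["logic"] = [(el.text or "").strip() for el in logic_els]
    ghosts = root.find("ghosts")
    data["ghosts"] = ([(g.text or "") for g in ghosts.findall("ghost")]
                      if ghosts is not None else [])
    return _transform_from_dict(data, where)


# ---------------------------------------------------------------------------
# public read/write


def _resolve_dialect(path: Path, dialect: str) -> str:
    if dialect in ("xml", "json"):
        return dialect
    if dialect != "auto":
        raise ValueError(f"unknown dialect {dialect!r} (use xml/json/auto)")
    suffix = path.suffix.lower()
    if suffix == ".slice":
        return "xml"
    if suffix == ".jslice":
        return "json"
    raise ValueError(
        f"cannot infer dialect from {path.name!r}; pass dialect='xml' or 'json'")


def read_transform(path, dialect: str = "auto") -> Transform:
    """Read a transform file; logic blocks are parsed immediately so syntax
    errors carry file context.  Validation errors (e.g. logic referencing an
    unmapped atom) raise :class:`TransformValidationError`."""
    path = Path(path)
    resolved = _resolve_dialect(path, dialect)
    text = path.read_text(encoding="utf-8")
    where = str(path)
    if resolved == "json":
        try:
            data = json.loads(text)
        except json.JSONDecodeError as exc:
            raise TransformFormatError(f"{where}: malformed JSON: {exc}") from exc
        t = _transform_from_dict(data, where)
    else:
        try:
            root = ET.fromstring(text)
        except ET.ParseError as exc:
            raise TransformFormatError(f"{where}: malformed XML: {exc}") from exc
        t = _transform_from_xml(root, where)
    _require_valid(t)
    return t


def write_transform(t: Transform, path, dialect: Optional[str] = None) -> None:
    """Write a transform; ``read_transform`` of the result reproduces the
    transform field-for-field.  Refuses to write invalid transforms."""
    path = Path(path)
    resolved = _resolve_dialect(path, dialect or "auto")
    _require_valid(t)
    if resolved == "json":
        path.write_text(json.dumps(_transform_to_dict(t), indent=2) + "\n",
                        encoding="utf-8")
    else:
        root = _transform_to_xml(t)
        ET.indent(root)
        path.write_text(ET.tostring(root, encoding="unicode") + "\n",
                        encoding="utf-8")
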