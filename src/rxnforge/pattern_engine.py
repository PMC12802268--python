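"""Keying-pattern compilation and matching.

Patterns are SMARTS with two atom-level extensions:

``z<n>``
    the atom has exactly *n* heteroatom neighbors (directly bonded atoms
    that are neither carbon nor hydrogen).
``^e<n>``
    experimental: the atom's valence-electron count (outer-shell electrons
    of the element minus formal charge) equals *n*.

Extensions are stripped before the core SMARTS is compiled with RDKit and
are applied as post-filters on candidate matches.  Matches are
symmetry-deduplicated: two matches covering the same set of molecule atoms
count once (first occurrence wins).
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional

from rdkit import Chem

__all__ = [
    "PatternError",
    "StructureError",
    "CompiledPattern",
    "MatchBinding",
    "GroupLibrary",
    "compile_pattern",
    "find_matches",
    "group_hits",
    "heteroatom_neighbor_count",
    "valence_electron_count",
]


class PatternError(ValueError):
    """Raised for uncompilable patterns or invalid extension usage."""


class StructureError(ValueError):
    """Raised for molecules that fail sanitization."""


# ---------------------------------------------------------------------------
# extension stripping

_EXT_RE = re.compile(r"(?:\^e(\d+))|(?:z(\d+))")
_ORGANIC_TWO = ("Cl", "Br")
_ORGANIC_ONE = set("BCNOPSFIbcnops*aA")


def _scan_atoms(smarts: str):
    """Yield (atom_ordinal, bracket_start, bracket_end) for bracket atoms and
    advance the ordinal across non-bracket atoms.  Bracket spans are inclusive
    of '[' and ']'."""
    i, ordinal = 0, 0
    out = []
    n = len(smarts)
    while i < n:
        c = smarts[i]
        if c == "[":
            depth = 1
            j = i + 1
            while j < n and depth:
                if smarts[j] == "[":
                    depth += 1
                elif smarts[j] == "]":
                    depth -= 1
                j += 1
            if depth:
                raise PatternError(f"unbalanced brackets in pattern {smarts!r}")
            out.append((ordinal, i, j))
            ordinal += 1
            i = j
        elif smarts[i:i + 2] in _ORGANIC_TWO:
            ordinal += 1
            i += 2
        elif c in _ORGANIC_ONE:
            ordinal += 1
            i += 1
        elif c == "%":
            i += 3  # %nn ring closure
        else:
            i += 1  # bonds, digits, parens, dots, maps never start an atom
    return out


def _strip_extensions(smarts: str):
    """Remove extension tokens, returning (core_smarts, constraints) where
    constraints are (atom_ordinal, kind, value) triples."""
    constraints: list[tuple[int, str, int]] = []
    spans = _scan_atoms(smarts)
    pieces: list[str] = []
    last = 0
    for ordinal, start, end in spans:
        body = smarts[start + 1:end - 1]
        # detach a trailing atom map so separator cleanup cannot eat it
        map_suffix = ""
        mm = re.search(r":(\d+)$", body)
        if mm:
            map_suffix = body[mm.start():]
            body = body[:mm.start()]
        found = list(_EXT_RE.finditer(body))
        if found:
            for m in found:
                if m.group(1) is not None:
                    constraints.append((ordinal, "ELECTRON_COUNT", int(m.group(1))))
                else:
                    constraints.append((ordinal, "HETEROATOM_NEIGHBOR_COUNT",
                                        int(m.group(2))))
            body = _EXT_RE.sub("", body)
            body = re.sub(r"[;&]{2,}", lambda m: m.group()[0], body)
            body = body.strip(";&,")
            if not body:
                body = "*"
        pieces.append(smarts[last:start])
        pieces.append(f"[{body}{map_suffix}]")
        last = end
    pieces.append(smarts[last:])
    core = "".join(pieces)
    if _EXT_RE.search(re.sub(r"\[[^\]]*\]", "", core)):
        raise PatternError(
            f"extension token outside an atom expression in {smarts!r} "
            "(atom-only attributes)")
    return core, constraints


# ---------------------------------------------------------------------------
# compiled pattern / binding


@dataclass
class CompiledPattern:
    source: str
    core_smarts: str
    query: Chem.Mol
    map_index_to_pattern_atom: dict[int, int]
    extension_constraints: list[tuple[int, str, str, int]]  # (pos, kind, cmp, value)

    @property
    def num_atoms(self) -> int:
        return self.query.GetNumAtoms()


@dataclass
class MatchBinding:
    """One keying-pattern match: the onpath/offpath partition of a molecule."""

    mol: Chem.Mol
    matched_atoms: tuple[int, ...]          # pattern atom position -> mol atom idx
    atom_map: dict[int, int]                # pattern map index -> mol atom idx
    onpath_atoms: frozenset[int]
    onpath_bonds: frozenset[int]
    offpath_atoms: frozenset[int]
    offpath_bonds: frozenset[int]

    def mol_atom(self, map_index: int) -> int:
        try:
            return self.atom_map[map_index]
        except KeyError:
            raise KeyError(
                f"map index {map_index} is not bound by this pattern "
                f"(bound: {sorted(self.atom_map)})") from None


def heteroatom_neighbor_count(atom: Chem.Atom) -> int:
    """Number of directly bonded neighbors that are neither C nor H."""
    return sum(1 for nb in atom.GetNeighbors()
               if nb.GetAtomicNum() not in (1, 6))


_PT = Chem.GetPeriodicTable()


def valence_electron_count(atom: Chem.Atom) -> int:
    """Outer-shell electrons of the element, adjusted for formal charge."""
    return _PT.GetNOuterElecs(atom.GetAtomicNum()) - atom.GetFormalCharge()


def compile_pattern(smarts_ext: str) -> CompiledPattern:
    """Compile an extended-SMARTS string.

    Standard SMARTS passes through unchanged; ``z<n>`` / ``^e<n>`` tokens are
    recorded as post-filter constraints.  Raises :class:`PatternError` on
    invalid SMARTS or an extension token outside an atom expression.
    """
    core, raw_constraints = _strip_extensions(smarts_ext)
    query = Chem.MolFromSmarts(core)
    if query is None:
        raise PatternError(f"invalid SMARTS: {smarts_ext!r} (core {core!r})")
    for pos, _, _ in raw_constraints:
        if pos >= query.GetNumAtoms():
            raise PatternError(
                f"extension constraint references atom {pos} beyond pattern "
                f"{smarts_ext!r}")
    amap = {}
    for atom in query.GetAtoms():
        n = atom.GetAtomMapNum()
        if n:
            amap[n] = atom.GetIdx()
    constraints = [(pos, kind, "==", value) for pos, kind, value in raw_constraints]
    return CompiledPattern(smarts_ext, core, query, amap, constraints)


def _constraint_ok(mol: Chem.Mol, match: tuple[int, ...],
                   constraint: tuple[int, str, str, int]) -> bool:
    pos, kind, cmp_, value = constraint
    atom = mol.GetAtomWithIdx(match[pos])
    if kind == "HETEROATOM_NEIGHBOR_COUNT":
        actual = heteroatom_neighbor_count(atom)
    elif kind == "ELECTRON_COUNT":
        actual = valence_electron_count(atom)
    else:  # pragma: no cover
        raise PatternError(f"unknown constraint kind {kind}")
    assert cmp_ == "=="
    return actual == value


def mol_from_smiles(smiles: str, ident: str = "?") -> Chem.Mol:
    """Parse and sanitize, raising :class:`StructureError` with the block id."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise StructureError(f"block {ident!r}: unparseable SMILES {smiles!r}")
    return mol


def find_matches(pattern: CompiledPattern, mol: Chem.Mol,
                 max_matches: int = 100000) -> list[MatchBinding]:
    """All symmetry-deduplicated matches of `pattern` in `mol`.

    Runs the raw (non-uniquified) substructure search, keeps the first match
    for each distinct matched-atom set, applies extension constraints as
    post-filters, and derives the onpath/offpath partition for each survivor.
    """
    raw = mol.GetSubstructMatches(pattern.query, uniquify=False,
                                  maxMatches=max_matches)
    bindings: list[MatchBinding] = []
    seen: set[frozenset[int]] = set()
    all_atoms = frozenset(range(mol.GetNumAtoms()))
    all_bonds = frozenset(range(mol.GetNumBonds()))
    for match in raw:
        key = frozenset(match)
        if key in seen:
            continue
        seen.add(key)
        if not all(_constraint_ok(mol, match, c)
                   for c in pattern.extension_constraints):
            continue
        onpath_bonds = set()
        for bond in pattern.query.GetBonds():
            a = match[bond.GetBeginAtomIdx()]
            b = match[bond.GetEndAtomIdx()]
            mb = mol.GetBondBetweenAtoms(a, b)
            if mb is not None:
                onpath_bonds.add(mb.GetIdx())
        amap = {m: match[i] for m, i in pattern.map_index_to_pattern_atom.items()}
        bindings.append(MatchBinding(
            mol=mol,
            matched_atoms=tuple(match),
            atom_map=amap,
            onpath_atoms=key,
            onpath_bonds=frozenset(onpath_bonds),
            offpath_atoms=all_atoms - key,
            offpath_bonds=all_bonds - frozenset(onpath_bonds),
        ))
    return bindings


# ---------------------------------------------------------------------------
# group library


class GroupLookupError(KeyError):
    pass


@dataclass
class GroupLibrary:
    """Named functional-group patterns with a designated origin atom.

    The on-disk form is a TSV of (name, SMARTS, origin_atom_position) rows
    with 0-based origin positions; see ``data/groups.tsv`` for the shipped
    defaults.
    """

    groups: dict[str, tuple[str, int, Chem.Mol]] = field(default_factory=dict)

    def add(self, name: str, smarts: str, origin: int) -> None:
        query = Chem.MolFromSmarts(smarts)
        if query is None:
            raise PatternError(f"group {name!r}: invalid SMARTS {smarts!r}")
        if not 0 <= origin < query.GetNumAtoms():
            raise PatternError(
                f"group {name!r}: origin position {origin} outside pattern")
        self.groups[name] = (smarts, origin, query)

    def __contains__(self, name: str) -> bool:
        return name in self.groups

    def names(self) -> list[str]:
        return sorted(self.groups)

    @classmethod
    def from_tsv(cls, path) -> "GroupLibrary":
        lib = cls()
        with open(path, newline="", encoding="utf-8") as fh:
            for row in csv.reader(fh, delimiter="\t"):
                if not row or row[0].startswith("#"):
                    continue
                name, smarts, origin = row[0], row[1], int(row[2])
                lib.add(name, smarts, origin)
        return lib

    @classmethod
    def default(cls) -> "GroupLibrary":
        ref = resources.files("rxnforge").joinpath("data/groups.tsv")
        with resources.as_file(ref) as path:
            return cls.from_tsv(path)


def group_hits(lib: GroupLibrary, name: str, mol: Chem.Mol) -> set[int]:
    """Molecule atom indices hit by the group's origin atom over all matches."""
    if name not in lib:
        raise GroupLookupError(
            f"unknown group {name!r}; known groups: {', '.join(lib.names())}")
    _, origin, query = lib.groups[name]
    return {match[origin] for match in mol.GetSubstructMatches(query)}
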