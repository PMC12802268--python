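"""Evaluation of logic programs against one pattern match.

One :class:`~rxnforge.pattern_engine.MatchBinding` plus one
:class:`~rxnforge.logic_lang.LogicProgram` yields a :class:`LogicOutcome`:
a kill flag, an ordered list of rating adjustments, ghost designations, and
an explainability trace.

Rating semantics: base 50; slightly/moderately/strongly/severely adjust by
5/10/20/35; the final value is clamped to [0, 100]; an application is
retained iff it is not killed and its final value is strictly positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Union

from rdkit import Chem

from .logic_lang import (
    Action, ActionKind, ClauseCombinator, Combinator, Condition, Container,
    Direction, EntityDesc, EntityKind, Loop, LogicProgram, Magnitude,
    NamedSetDef, Predicate, PredicateKind, Quantifier, Relation, Statement,
    Subject, SubjectKind, Where, _statement_text,
)
from .pattern_engine import (
    GroupLibrary, MatchBinding, group_hits, heteroatom_neighbor_count,
)

__all__ = [
    "MAGNITUDE_STEPS", "Rating", "LogicOutcome", "EvalEnv",
    "LogicEvalError", "LogicTypeError",
    "eval_subject", "eval_condition", "run_statement", "run_loop",
    "run_program",
]

MAGNITUDE_STEPS: dict[Magnitude, int] = {
    Magnitude.SLIGHTLY: 5,
    Magnitude.MODERATELY: 10,
    Magnitude.STRONGLY: 20,
    Magnitude.SEVERELY: 35,
}

BASE_RATING = 50


class LogicEvalError(Exception):
    pass


class LogicTypeError(LogicEvalError):
    """Predicate applied to an object class it cannot describe."""


# ---------------------------------------------------------------------------
# chemical objects


@dataclass(frozen=True)
class AtomObj:
    idx: int


@dataclass(frozen=True)
class BondObj:
    idx: int


@dataclass(frozen=True)
class RingObj:
    atoms: tuple[int, ...]


@dataclass(frozen=True)
class MolObj:
    pass


ChemObject = Union[AtomObj, BondObj, RingObj, MolObj]


# ---------------------------------------------------------------------------
# outcome types


@dataclass
class Rating:
    base: int = BASE_RATING
    deltas: list[tuple[Direction, Magnitude, int]] = field(default_factory=list)
    killed: bool = False

    def adjust(self, direction: Direction, magnitude: Magnitude) -> None:
        step = MAGNITUDE_STEPS[magnitude]
        self.deltas.append((direction, magnitude, step))

    def kill(self) -> None:
        self.killed = True

    @property
    def value(self) -> int:
        total = self.base
        for direction, _, step in self.deltas:
            total += step if direction is Direction.RAISE else -step
        return max(0, min(100, total))

    @property
    def retained(self) -> bool:
        return not self.killed and self.value > 0


@dataclass
class LogicOutcome:
    rating: Rating = field(default_factory=Rating)
    ghosts: list[str] = field(default_factory=list)
    trace: list[tuple[str, bool]] = field(default_factory=list)


@dataclass
class EvalEnv:
    bindings: dict[str, ChemObject] = field(default_factory=dict)
    named_sets: dict[str, tuple[ChemObject, ...]] = field(default_factory=dict)

    def lookup(self, name: str) -> ChemObject:
        try:
            return self.bindings[name]
        except KeyError:
            raise LogicEvalError(f"unbound variable {name!r}") from None


# ---------------------------------------------------------------------------
# subjects


def eval_subject(subject: Subject, binding: MatchBinding,
                 env: Optional[EvalEnv] = None) -> list[ChemObject]:
    """Resolve a subject to its chemical-object set (before any where filter)."""
    env = env or EvalEnv()
    mol = binding.mol
    if subject.kind is SubjectKind.ATOM:
        return [AtomObj(binding.mol_atom(subject.atom_refs[0]))]
    if subject.kind is SubjectKind.ALPHA_TO_ATOM:
        center = binding.mol_atom(subject.atom_refs[0])
        atom = mol.GetAtomWithIdx(center)
        return [AtomObj(nb.GetIdx()) for nb in atom.GetNeighbors()]
    if subject.kind is SubjectKind.BOND:
        i = binding.mol_atom(subject.atom_refs[0])
        j = binding.mol_atom(subject.atom_refs[1])
        bond = mol.GetBondBetweenAtoms(i, j)
        if bond is None:
            raise LogicEvalError(
                f"no bond between mapped atoms {subject.atom_refs[0]} and "
                f"{subject.atom_refs[1]} (transform/pattern inconsistency)")
        return [BondObj(bond.GetIdx())]
    if subject.kind is SubjectKind.MOLECULE:
        return [MolObj()]
    return [env.lookup(subject.var_name)]


def _where_keeps(obj: ChemObject, where: Where, binding: MatchBinding) -> bool:
    if where is Where.NONE:
        return True
    if isinstance(obj, AtomObj):
        target = binding.offpath_atoms if where is Where.OFFPATH else binding.onpath_atoms
        return obj.idx in target
    if isinstance(obj, BondObj):
        target = binding.offpath_bonds if where is Where.OFFPATH else binding.onpath_bonds
        return obj.idx in target
    if isinstance(obj, RingObj):
        atoms = set(obj.atoms)
        if where is Where.OFFPATH:
            return atoms.isdisjoint(binding.onpath_atoms)
        return atoms <= binding.onpath_atoms
    return True  # MolObj is location-free


# ---------------------------------------------------------------------------
# predicates


class _Ctx:
    def __init__(self, binding: MatchBinding, env: EvalEnv,
                 group_library: Optional[GroupLibrary]):
        self.binding = binding
        self.env = env
        self.mol = binding.mol
        self._group_library = group_library
        self._group_cache: dict[str, set[int]] = {}

    @property
    def group_library(self) -> GroupLibrary:
        if self._group_library is None:
            self._group_library = GroupLibrary.default()
        return self._group_library

    def origins(self, name: str) -> set[int]:
        if name not in self._group_cache:
            self._group_cache[name] = group_hits(self.group_library, name, self.mol)
        return self._group_cache[name]


_ELEMENT_QUAL = {f"{name} atom": num for name, num in {
    "hydrogen": 1, "boron": 5, "carbon": 6, "nitrogen": 7, "oxygen": 8,
    "fluorine": 9, "silicon": 14, "phosphorus": 15, "sulfur": 16,
    "chlorine": 17, "selenium": 34, "bromine": 35, "iodine": 53,
}.items()}

_HALOGENS = {9, 17, 35, 53}
_CENTER_ORDER = {"primary center": 1, "secondary center": 2,
                 "tertiary center": 3, "quaternary center": 4}


def _qualitative_on_atom(name: str, atom: Chem.Atom, ctx: _Ctx) -> bool:
    if name in _ELEMENT_QUAL:
        return atom.GetAtomicNum() == _ELEMENT_QUAL[name]
    if name == "aromatic":
        return atom.GetIsAromatic()
    if name == "aliphatic":
        return not atom.GetIsAromatic()
    if name == "in ring":
        return atom.IsInRing()
    if name == "charged":
        return atom.GetFormalCharge() != 0
    if name == "positively charged":
        return atom.GetFormalCharge() > 0
    if name == "negatively charged":
        return atom.GetFormalCharge() < 0
    if name == "halogen":
        return atom.GetAtomicNum() in _HALOGENS
    if name == "heteroatom":
        return atom.GetAtomicNum() not in (1, 6)
    if name == "terminal":
        return atom.GetDegree() <= 1
    if name in _CENTER_ORDER:
        carbons = sum(1 for nb in atom.GetNeighbors() if nb.GetAtomicNum() == 6)
        return atom.GetAtomicNum() == 6 and carbons == _CENTER_ORDER[name]
    raise LogicTypeError(f"qualitative property {name!r} is not defined for atoms")


def _qualitative_on_bond(name: str, bond: Chem.Bond) -> bool:
    if name == "aromatic":
        return bond.GetIsAromatic()
    if name == "aliphatic":
        return not bond.GetIsAromatic()
    if name == "in ring":
        return bond.IsInRing()
    if name == "single bond":
        return bond.GetBondType() == Chem.BondType.SINGLE
    if name == "double bond":
        return bond.GetBondType() == Chem.BondType.DOUBLE
    if name == "triple bond":
        return bond.GetBondType() == Chem.BondType.TRIPLE
    raise LogicTypeError(f"qualitative property {name!r} is not defined for bonds")


def _qualitative_on_ring(name: str, ring: RingObj, ctx: _Ctx) -> bool:
    if name == "aromatic":
        return all(ctx.mol.GetAtomWithIdx(i).GetIsAromatic() for i in ring.atoms)
    if name == "aliphatic":
        return not _qualitative_on_ring("aromatic", ring, ctx)
    raise LogicTypeError(f"qualitative property {name!r} is not defined for rings")


def _entity_count_on_atom(entity: EntityDesc, atom: Chem.Atom, ctx: _Ctx) -> int:
    if entity.kind is EntityKind.HYDROGEN:
        return atom.GetTotalNumHs()
    if entity.kind is EntityKind.ELEMENT:
        num = _ELEMENT_QUAL[f"{entity.name} atom"]
        if num == 1:
            return atom.GetTotalNumHs()
        return sum(1 for nb in atom.GetNeighbors() if nb.GetAtomicNum() == num)
    if entity.kind is EntityKind.HETEROATOM:
        return heteroatom_neighbor_count(atom)
    if entity.kind is EntityKind.POSITIVE_CHARGE:
        return max(0, atom.GetFormalCharge())
    if entity.kind is EntityKind.NEGATIVE_CHARGE:
        return max(0, -atom.GetFormalCharge())
    if entity.kind is EntityKind.RING:
        return ctx.mol.GetRingInfo().NumAtomRings(atom.GetIdx())
    if entity.kind is EntityKind.ATOM:
        return atom.GetDegree()
    if entity.kind is EntityKind.GROUP:
        origins = ctx.origins(entity.name)
        return sum(1 for nb in atom.GetNeighbors() if nb.GetIdx() in origins)
    if entity.kind is EntityKind.BOND:
        return atom.GetDegree()
    raise LogicTypeError(f"cannot count {entity.kind.value!r} on an atom")


def _entity_count_on_mol(entity: EntityDesc, ctx: _Ctx) -> int:
    mol = ctx.mol
    if entity.kind is EntityKind.HYDROGEN:
        return sum(a.GetTotalNumHs() for a in mol.GetAtoms())
    if entity.kind is EntityKind.ELEMENT:
        num = _ELEMENT_QUAL[f"{entity.name} atom"]
        if num == 1:
            return sum(a.GetTotalNumHs() for a in mol.GetAtoms())
        return sum(1 for a in mol.GetAtoms() if a.GetAtomicNum() == num)
    if entity.kind is EntityKind.HETEROATOM:
        return sum(1 for a in mol.GetAtoms() if a.GetAtomicNum() not in (1, 6))
    if entity.kind is EntityKind.POSITIVE_CHARGE:
        return sum(max(0, a.GetFormalCharge()) for a in mol.GetAtoms())
    if entity.kind is EntityKind.NEGATIVE_CHARGE:
        return sum(max(0, -a.GetFormalCharge()) for a in mol.GetAtoms())
    if entity.kind is EntityKind.RING:
        return mol.GetRingInfo().NumRings()
    if entity.kind is EntityKind.ATOM:
        return mol.GetNumAtoms()
    if entity.kind is EntityKind.BOND:
        return mol.GetNumBonds()
    if entity.kind is EntityKind.GROUP:
        return len(ctx.origins(entity.name))
    raise LogicTypeError(f"cannot count {entity.kind.value!r} on a molecule")


def _compare(actual: int, quantifier: Quantifier, count: int) -> bool:
    if quantifier is Quantifier.AT_LEAST:
        return actual >= count
    if quantifier is Quantifier.AT_MOST:
        return actual <= count
    return actual == count


def _predicate_on_object(pred: Predicate, obj: ChemObject, ctx: _Ctx) -> bool:
    if pred.kind is PredicateKind.GROUP_ORIGIN:
        if not isinstance(obj, AtomObj):
            raise LogicTypeError("'origin of ... group' applies to atoms only")
        result = obj.idx in ctx.origins(pred.name)
    elif pred.kind is PredicateKind.QUALITATIVE:
        if isinstance(obj, AtomObj):
            result = _qualitative_on_atom(pred.name, ctx.mol.GetAtomWithIdx(obj.idx), ctx)
        elif isinstance(obj, BondObj):
            result = _qualitative_on_bond(pred.name, ctx.mol.GetBondWithIdx(obj.idx))
        elif isinstance(obj, RingObj):
            result = _qualitative_on_ring(pred.name, obj, ctx)
        else:
            raise LogicTypeError(
                f"qualitative property {pred.name!r} does not apply to a molecule")
    else:  # QUANTITATIVE
        if isinstance(obj, AtomObj):
            actual = _entity_count_on_atom(pred.entity, ctx.mol.GetAtomWithIdx(obj.idx), ctx)
        elif isinstance(obj, MolObj):
            actual = _entity_count_on_mol(pred.entity, ctx)
        elif isinstance(obj, RingObj):
            if pred.entity.kind is EntityKind.ATOM:
                actual = len(obj.atoms)
            else:
                raise LogicTypeError("rings only count their atoms")
        else:
            raise LogicTypeError("quantitative predicates do not apply to bonds")
        result = _compare(actual, pred.quantifier, pred.count)
    return (not result) if pred.negated else result


def _predicates_on_object(cond: Condition, obj: ChemObject, ctx: _Ctx) -> bool:
    if cond.predicate_combinator is Combinator.AND:
        return all(_predicate_on_object(p, obj, ctx) for p in cond.predicates)
    return any(_predicate_on_object(p, obj, ctx) for p in cond.predicates)


def eval_condition(cond: Condition, binding: MatchBinding,
                   env: Optional[EvalEnv] = None,
                   group_library: Optional[GroupLibrary] = None) -> bool:
    """True iff the condition holds under the binding.

    Each subject resolves to an object set, filtered by the where clause; a
    subject is satisfied when at least one surviving object satisfies the
    predicate list (an emptied set is therefore false).  Subject truths
    combine with the subject combinator.
    """
    env = env or EvalEnv()
    ctx = _Ctx(binding, env, group_library)

    def subject_truth(subject: Subject) -> bool:
        objs = [o for o in eval_subject(subject, binding, env)
                if _where_keeps(o, cond.where, binding)]
        return any(_predicates_on_object(cond, o, ctx) for o in objs)

    if cond.subject_combinator is Combinator.AND:
        return all(subject_truth(s) for s in cond.subjects)
    return any(subject_truth(s) for s in cond.subjects)


# ---------------------------------------------------------------------------
# statements, loops, programs


def _apply_action(action: Action, out: LogicOutcome) -> None:
    if action.kind is ActionKind.KILL:
        out.rating.kill()
    elif action.kind is ActionKind.ADJUST_RATING:
        out.rating.adjust(action.direction, action.magnitude)
    else:
        out.ghosts.append(action.ghost_fragment)


def run_statement(statement: Statement, binding: MatchBinding, env: EvalEnv,
                  out: LogicOutcome,
                  group_library: Optional[GroupLibrary] = None) -> LogicOutcome:
    """Evaluate clauses left-to-right (short-circuiting) and fire the action
    at most once; the trace records the evaluation."""
    truth: Optional[bool] = None
    for comb, cond in statement.clauses:
        if comb is ClauseCombinator.FIRST:
            truth = eval_condition(cond, binding, env, group_library)
        elif comb is ClauseCombinator.AND_IF:
            if truth:
                truth = eval_condition(cond, binding, env, group_library)
        else:  # OR_IF
            if not truth:
                truth = eval_condition(cond, binding, env, group_library)
    if truth:
        _apply_action(statement.action, out)
    out.trace.append((_statement_text(statement), bool(truth)))
    return out


def _enumerate_iterand(entity: EntityDesc, where: Where, container: Container,
                       container_name: Optional[str], binding: MatchBinding,
                       env: EvalEnv, ctx: _Ctx) -> list[ChemObject]:
    mol = binding.mol
    objs: list[ChemObject]
    if container is Container.NAMED_SET:
        try:
            pool = list(env.named_sets[container_name])
        except KeyError:
            raise LogicEvalError(f"unknown named set {container_name!r}") from None
        objs = [o for o in pool if _iterand_matches(entity, o, ctx)]
    elif container is Container.RINGS or entity.kind is EntityKind.RING:
        objs = [RingObj(tuple(sorted(r)))
                for r in mol.GetRingInfo().AtomRings()]
    elif entity.kind is EntityKind.BOND:
        objs = [BondObj(b.GetIdx()) for b in mol.GetBonds()]
    elif entity.kind is EntityKind.GROUP:
        objs = [AtomObj(i) for i in sorted(ctx.origins(entity.name))]
    else:
        objs = [AtomObj(a.GetIdx()) for a in mol.GetAtoms()
                if _iterand_matches(entity, AtomObj(a.GetIdx()), ctx)]
    return [o for o in objs if _where_keeps(o, where, binding)]


def _iterand_matches(entity: EntityDesc, obj: ChemObject, ctx: _Ctx) -> bool:
    if isinstance(obj, AtomObj):
        atom = ctx.mol.GetAtomWithIdx(obj.idx)
        if entity.kind is EntityKind.ATOM:
            return True
        if entity.kind is EntityKind.ELEMENT:
            return atom.GetAtomicNum() == _ELEMENT_QUAL[f"{entity.name} atom"]
        if entity.kind is EntityKind.HETEROATOM:
            return atom.GetAtomicNum() not in (1, 6)
        if entity.kind is EntityKind.GROUP:
            return obj.idx in ctx.origins(entity.name)
        return False
    if isinstance(obj, BondObj):
        return entity.kind is EntityKind.BOND
    if isinstance(obj, RingObj):
        return entity.kind is EntityKind.RING
    return False


def run_loop(loop: Loop, binding: MatchBinding, env: EvalEnv,
             out: LogicOutcome,
             group_library: Optional[GroupLibrary] = None) -> LogicOutcome:
    """Bind the loop variable to each matching object in canonical order and
    run the body; the binding is removed afterwards."""
    ctx = _Ctx(binding, env, group_library)
    objs = _enumerate_iterand(loop.iterand, loop.where, loop.container,
                              loop.container_name, binding, env, ctx)
    for obj in objs:
        env.bindings[loop.var_name] = obj
        try:
            _run_items(loop.body.items, binding, env, out, group_library)
        finally:
            del env.bindings[loop.var_name]
        if out.rating.killed:
            break
    return out


def _run_items(items, binding: MatchBinding, env: EvalEnv, out: LogicOutcome,
               group_library: Optional[GroupLibrary]) -> None:
    for item in items:
        if out.rating.killed:
            return  # kill is monotone; short-circuit the rest
        if isinstance(item, Statement):
            run_statement(item, binding, env, out, group_library)
        elif isinstance(item, Loop):
            run_loop(item, binding, env, out, group_library)
        elif isinstance(item, NamedSetDef):
            ctx = _Ctx(binding, env, group_library)
            env.named_sets[item.name] = tuple(_enumerate_iterand(
                item.entity, item.where, Container.MOLECULE, None,
                binding, env, ctx))
        else:  # pragma: no cover
            raise TypeError(f"unknown program item {item!r}")


def run_program(program: LogicProgram, binding: MatchBinding,
                group_library: Optional[GroupLibrary] = None) -> LogicOutcome:
    """Run a whole program against one binding, starting from a fresh rating."""
    out = LogicOutcome()
    env = EvalEnv()
    _run_items(program.items, binding, env, out, group_library)
    return out
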