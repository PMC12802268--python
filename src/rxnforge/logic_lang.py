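"""Lexer, parser, AST and canonical serializer for the transform logic language.

The language is a flat, IFTTT-style rule notation evaluated against one
pattern match in a candidate molecule::

    if <subject> <relation> <predicate> [<where>] then <action>

Statements combine clauses with ``and if`` / ``or if`` (strict left-to-right,
left-associative, short-circuiting).  Subjects and predicates combine with
``and`` / ``or``.  Loops iterate chemical objects::

    foreach <entity> [<where>] defined as <var> in <container> { ... }

``//`` starts a comment; newlines are plain whitespace, so one statement may
span several lines.  Keywords are case-insensitive.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterator, Optional, Union


# ---------------------------------------------------------------------------
# errors


class LogicError(Exception):
    """Base class for logic-language errors."""


class LogicLexError(LogicError):
    def __init__(self, message: str, line: int, col: int):
        super().__init__(f"{message} (line {line}, column {col})")
        self.line = line
        self.col = col


class LogicSyntaxError(LogicError):
    def __init__(self, message: str, line: int = 0, col: int = 0):
        loc = f" (line {line}, column {col})" if line else ""
        super().__init__(f"{message}{loc}")
        self.line = line
        self.col = col


class LogicScopeError(LogicError):
    pass


# ---------------------------------------------------------------------------
# AST enums


class SubjectKind(Enum):
    ATOM = "atom"
    ALPHA_TO_ATOM = "alpha_to_atom"
    BOND = "bond"
    MOLECULE = "molecule"
    VARIABLE = "variable"


class Relation(Enum):
    IS = "is"
    HAS = "has"


class PredicateKind(Enum):
    QUALITATIVE = "qualitative"
    QUANTITATIVE = "quantitative"
    GROUP_ORIGIN = "group_origin"


class Quantifier(Enum):
    AT_LEAST = "at least"
    AT_MOST = "at most"
    EXACTLY = "exactly"


class EntityKind(Enum):
    ELEMENT = "element"
    HETEROATOM = "heteroatom"
    HYDROGEN = "hydrogen"
    POSITIVE_CHARGE = "positive charge"
    NEGATIVE_CHARGE = "negative charge"
    RING = "ring"
    BOND = "bond"
    ATOM = "atom"
    GROUP = "group"


class Combinator(Enum):
    AND = "and"
    OR = "or"


class Where(Enum):
    NONE = ""
    OFFPATH = "offpath"
    ONPATH = "onpath"


class ClauseCombinator(Enum):
    FIRST = "if"
    AND_IF = "and if"
    OR_IF = "or if"


class ActionKind(Enum):
    KILL = "kill"
    ADJUST_RATING = "adjust_rating"
    GHOST = "ghost"


class Direction(Enum):
    RAISE = "raise"
    LOWER = "lower"


class Magnitude(Enum):
    SLIGHTLY = "slightly"
    MODERATELY = "moderately"
    STRONGLY = "strongly"
    SEVERELY = "severely"


class Container(Enum):
    MOLECULE = "molecule"
    RINGS = "rings"
    NAMED_SET = "named_set"


# ---------------------------------------------------------------------------
# AST nodes


@dataclass(frozen=True)
class Subject:
    kind: SubjectKind
    atom_refs: tuple[int, ...] = ()
    var_name: Optional[str] = None

    def __post_init__(self):
        if self.kind is SubjectKind.BOND:
            if len(self.atom_refs) != 2 or self.atom_refs[0] == self.atom_refs[1]:
                raise ValueError("BOND subject needs two distinct map indices")
        elif self.kind in (SubjectKind.ATOM, SubjectKind.ALPHA_TO_ATOM):
            if len(self.atom_refs) != 1:
                raise ValueError(f"{self.kind.name} subject needs exactly one map index")


@dataclass(frozen=True)
class EntityDesc:
    """A countable / iterable chemical-object descriptor ('carbon atom',
    'heteroatom', 'positive charge', 'amine1 group', ...)."""

    kind: EntityKind
    name: Optional[str] = None  # element name or group name


@dataclass(frozen=True)
class Predicate:
    kind: PredicateKind
    name: Optional[str] = None            # qualitative property or group name
    quantifier: Optional[Quantifier] = None
    count: Optional[int] = None
    entity: Optional[EntityDesc] = None
    negated: bool = False

    def __post_init__(self):
        quant = (self.quantifier, self.count, self.entity)
        if self.kind is PredicateKind.QUANTITATIVE:
            if any(v is None for v in quant):
                raise ValueError("quantitative predicate needs quantifier/count/entity")
        elif any(v is not None for v in quant):
            raise ValueError("quantifier/count/entity only valid on quantitative predicates")


@dataclass(frozen=True)
class Condition:
    subjects: tuple[Subject, ...]
    relation: Relation
    predicates: tuple[Predicate, ...]
    subject_combinator: Combinator = Combinator.OR
    predicate_combinator: Combinator = Combinator.AND
    where: Where = Where.NONE

    def __post_init__(self):
        if not self.subjects or not self.predicates:
            raise ValueError("condition needs at least one subject and one predicate")
        # combinators are unobservable on singleton lists; normalize them so
        # structural equality matches the canonical serialized form
        if len(self.subjects) == 1:
            object.__setattr__(self, "subject_combinator", Combinator.OR)
        if len(self.predicates) == 1:
            object.__setattr__(self, "predicate_combinator", Combinator.AND)
        for p in self.predicates:
            quantitative = p.kind is PredicateKind.QUANTITATIVE
            if (self.relation is Relation.HAS) != quantitative:
                raise ValueError(
                    "'is' pairs with qualitative/group predicates, 'has' with quantitative"
                )


@dataclass(frozen=True)
class Action:
    kind: ActionKind
    direction: Optional[Direction] = None
    magnitude: Optional[Magnitude] = None
    ghost_fragment: Optional[str] = None

    def __post_init__(self):
        if self.kind is ActionKind.ADJUST_RATING:
            if self.direction is None or self.magnitude is None:
                raise ValueError("rating adjustment needs direction and magnitude")
        elif self.magnitude is not None or self.direction is not None:
            raise ValueError("direction/magnitude only valid on rating adjustments")
        if (self.kind is ActionKind.GHOST) != (self.ghost_fragment is not None):
            raise ValueError("ghost_fragment present iff kind is GHOST")


@dataclass(frozen=True)
class Statement:
    clauses: tuple[tuple[ClauseCombinator, Condition], ...]
    action: Action

    def __post_init__(self):
        if not self.clauses:
            raise ValueError("statement needs at least one clause")
        if self.clauses[0][0] is not ClauseCombinator.FIRST:
            raise ValueError("first clause must have combinator FIRST")
        if any(c is ClauseCombinator.FIRST for c, _ in self.clauses[1:]):
            raise ValueError("only the first clause may have combinator FIRST")


@dataclass(frozen=True)
class NamedSetDef:
    name: str
    entity: EntityDesc
    where: Where = Where.NONE


@dataclass(frozen=True)
class Loop:
    iterand: EntityDesc
    where: Where
    var_name: str
    container: Container
    body: "LogicProgram"
    container_name: Optional[str] = None

    def __post_init__(self):
        if (self.container is Container.NAMED_SET) != (self.container_name is not None):
            raise ValueError("container_name present iff container is NAMED_SET")


@dataclass(frozen=True)
class LogicProgram:
    items: tuple[Union[Statement, Loop, NamedSetDef], ...] = ()

    def referenced_map_indices(self) -> set[int]:
        """All pattern map indices mentioned by any subject, at any depth."""
        out: set[int] = set()

        def visit(items):
            for it in items:
                if isinstance(it, Statement):
                    for _, cond in it.clauses:
                        for s in cond.subjects:
                            out.update(s.atom_refs)
                elif isinstance(it, Loop):
                    visit(it.body.items)

        visit(self.items)
        return out

    def referenced_groups(self) -> set[str]:
        """All group names referenced by predicates or entities, at any depth."""
        out: set[str] = set()

        def visit_pred(p: Predicate):
            if p.kind is PredicateKind.GROUP_ORIGIN:
                out.add(p.name)
            if p.entity is not None and p.entity.kind is EntityKind.GROUP:
                out.add(p.entity.name)

        def visit(items):
            for it in items:
                if isinstance(it, Statement):
                    for _, cond in it.clauses:
                        for p in cond.predicates:
                            visit_pred(p)
                elif isinstance(it, Loop):
                    if it.iterand.kind is EntityKind.GROUP:
                        out.add(it.iterand.name)
                    visit(it.body.items)
                elif isinstance(it, NamedSetDef):
                    if it.entity.kind is EntityKind.GROUP:
                        out.add(it.entity.name)

        visit(self.items)
        return out


# ---------------------------------------------------------------------------
# lexer


@dataclass(frozen=True)
class Token:
    kind: str  # WORD | INT | STRING | LBRACE | RBRACE | EOF
    value: str
    line: int
    col: int


_TOKEN_RE = re.compile(
    r"""
    (?P<ws>\s+)
  | (?P<comment>//[^\n]*)
  | (?P<int>\d+)
  | (?P<word>[A-Za-z_][A-Za-z0-9_]*)
  | (?P<string>"[^"\n]*")
  | (?P<lbrace>\{)
  | (?P<rbrace>\})
    """,
    re.VERBOSE,
)


def tokenize(text: str) -> list[Token]:
    """Tokenize logic source.  Comments and whitespace are dropped; an
    illegal character raises :class:`LogicLexError` with its position."""
    tokens: list[Token] = []
    line, col = 1, 1
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None:
            raise LogicLexError(f"illegal character {text[pos]!r}", line, col)
        kind = m.lastgroup
        value = m.group()
        if kind == "int":
            tokens.append(Token("INT", value, line, col))
        elif kind == "word":
            tokens.append(Token("WORD", value, line, col))
        elif kind == "string":
            tokens.append(Token("STRING", value[1:-1], line, col))
        elif kind == "lbrace":
            tokens.append(Token("LBRACE", value, line, col))
        elif kind == "rbrace":
            tokens.append(Token("RBRACE", value, line, col))
        # ws / comment dropped
        nl = value.count("\n")
        if nl:
            line += nl
            col = len(value) - value.rfind("\n")
        else:
            col += len(value)
        pos = m.end()
    tokens.append(Token("EOF", "", line, col))
    return tokens


# ---------------------------------------------------------------------------
# vocabulary tables (closed; unknown words are parse errors)

ELEMENTS: dict[str, int] = {
    "hydrogen": 1, "boron": 5, "carbon": 6, "nitrogen": 7, "oxygen": 8,
    "fluorine": 9, "silicon": 14, "phosphorus": 15, "sulfur": 16,
    "chlorine": 17, "selenium": 34, "bromine": 35, "iodine": 53,
}

NUMBER_WORDS: dict[str, int] = {
    "one": 1, "two": 2, "three": 3, "four": 4, "five": 5,
    "six": 6, "seven": 7, "eight": 8, "nine": 9, "ten": 10,
}

#: qualitative property phrases, canonical name -> accepted word tuples
QUALITATIVE_PHRASES: dict[tuple[str, ...], str] = {
    ("aromatic",): "aromatic",
    ("aliphatic",): "aliphatic",
    ("in", "ring"): "in ring",
    ("in", "a", "ring"): "in ring",
    ("charged",): "charged",
    ("positively", "charged"): "positively charged",
    ("negatively", "charged"): "negatively charged",
    ("primary", "center"): "primary center",
    ("secondary", "center"): "secondary center",
    ("tertiary", "center"): "tertiary center",
    ("quaternary", "center"): "quaternary center",
    ("halogen",): "halogen",
    ("heteroatom",): "heteroatom",
    ("terminal",): "terminal",
    ("single", "bond"): "single bond",
    ("double", "bond"): "double bond",
    ("triple", "bond"): "triple bond",
}

_RESERVED = {
    "if", "then", "and", "or", "is", "are", "has", "have", "not", "the",
    "kill", "raise", "lower", "rating", "ghost", "foreach", "for", "each",
    "defined", "as", "in", "set", "molecule", "rings", "atom", "atoms",
    "bond", "bonds", "alpha", "to", "between", "offpath", "onpath",
    "origin", "of", "group", "groups", "at", "least", "most", "exactly",
    "slightly", "moderately", "strongly", "severely", "attached", "it",
} | set(NUMBER_WORDS)


def _plural_forms(word: str) -> set[str]:
    return {word, word + "s"}


# element word -> canonical name (accepts plural)
_ELEMENT_WORDS: dict[str, str] = {}
for _name in ELEMENTS:
    for w in _plural_forms(_name):
        _ELEMENT_WORDS[w] = _name

_ENTITY_SIMPLE: dict[str, EntityDesc] = {}
for _w in _plural_forms("heteroatom"):
    _ENTITY_SIMPLE[_w] = EntityDesc(EntityKind.HETEROATOM)
for _w in _plural_forms("ring"):
    _ENTITY_SIMPLE[_w] = EntityDesc(EntityKind.RING)
for _w in _plural_forms("bond"):
    _ENTITY_SIMPLE[_w] = EntityDesc(EntityKind.BOND)
for _w in _plural_forms("atom"):
    _ENTITY_SIMPLE[_w] = EntityDesc(EntityKind.ATOM)


# ---------------------------------------------------------------------------
# parser


class _Parser:
    def __init__(self, tokens: list[Token]):
        self.tokens = tokens
        self.pos = 0

    # -- token helpers ----------------------------------------------------

    def peek(self, offset: int = 0) -> Token:
        i = min(self.pos + offset, len(self.tokens) - 1)
        return self.tokens[i]

    def peek_word(self, offset: int = 0) -> Optional[str]:
        t = self.peek(offset)
        return t.value.lower() if t.kind == "WORD" else None

    def next(self) -> Token:
        t = self.tokens[self.pos]
        if t.kind != "EOF":
            self.pos += 1
        return t

    def error(self, msg: str) -> LogicSyntaxError:
        t = self.peek()
        near = t.value if t.kind != "EOF" else "end of input"
        return LogicSyntaxError(f"{msg}, near {near!r}", t.line, t.col)

    def expect_word(self, *words: str) -> str:
        w = self.peek_word()
        if w not in words:
            raise self.error(f"expected {' / '.join(repr(x) for x in words)}")
        self.next()
        return w

    def accept_word(self, *words: str) -> Optional[str]:
        w = self.peek_word()
        if w in words:
            self.next()
            return w
        return None

    def expect_int(self) -> int:
        t = self.peek()
        if t.kind == "INT":
            self.next()
            return int(t.value)
        if t.kind == "WORD" and t.value.lower() in NUMBER_WORDS:
            self.next()
            return NUMBER_WORDS[t.value.lower()]
        raise self.error("expected a number")

    def expect_identifier(self) -> str:
        t = self.peek()
        if t.kind != "WORD" or t.value.lower() in _RESERVED:
            raise self.error("expected an identifier")
        self.next()
        return t.value

    # -- program ----------------------------------------------------------

    def parse_program(self, scope: Optional[set[str]] = None) -> LogicProgram:
        scope = set(scope or ())
        items: list[Union[Statement, Loop, NamedSetDef]] = []
        while self.peek().kind != "EOF" and self.peek().kind != "RBRACE":
            items.append(self.parse_item(scope))
        return LogicProgram(tuple(items))

    def parse_item(self, scope: set[str]) -> Union[Statement, Loop, NamedSetDef]:
        w = self.peek_word()
        if w == "if":
            return self.parse_statement(scope)
        if w == "foreach" or (w == "for" and self.peek_word(1) == "each"):
            return self.parse_loop(scope)
        if w == "set":
            return self.parse_named_set(scope)
        raise self.error("expected 'if', 'foreach' or 'set'")

    # -- statements -------------------------------------------------------

    def parse_statement(self, scope: set[str]) -> Statement:
        self.expect_word("if")
        clauses = [(ClauseCombinator.FIRST, self.parse_condition(scope))]
        while True:
            w = self.peek_word()
            if w in ("and", "or") and self.peek_word(1) == "if":
                self.next()
                self.next()
                comb = ClauseCombinator.AND_IF if w == "and" else ClauseCombinator.OR_IF
                clauses.append((comb, self.parse_condition(scope)))
            else:
                break
        self.expect_word("then")
        action = self.parse_action()
        return Statement(tuple(clauses), action)

    def parse_condition(self, scope: set[str]) -> Condition:
        subjects = [self.parse_subject(scope)]
        subj_comb: Optional[Combinator] = None
        while True:
            w = self.peek_word()
            if w in ("and", "or") and self._subject_ahead(1):
                self.next()
                comb = Combinator.AND if w == "and" else Combinator.OR
                if subj_comb is not None and comb is not subj_comb:
                    raise self.error("mixed 'and'/'or' between subjects")
                subj_comb = comb
                subjects.append(self.parse_subject(scope))
            else:
                break

        where = Where.NONE
        w = self.accept_word("offpath", "onpath")
        if w:
            where = Where(w)

        rel_word = self.expect_word("is", "are", "has", "have")
        relation = Relation.IS if rel_word in ("is", "are") else Relation.HAS

        predicates = [self.parse_predicate(relation)]
        pred_comb: Optional[Combinator] = None
        while True:
            w = self.peek_word()
            if w in ("and", "or") and self.peek_word(1) != "if":
                self.next()
                comb = Combinator.AND if w == "and" else Combinator.OR
                if pred_comb is not None and comb is not pred_comb:
                    raise self.error("mixed 'and'/'or' between predicates")
                pred_comb = comb
                predicates.append(self.parse_predicate(relation))
            else:
                break

        w = self.accept_word("offpath", "onpath")
        if w:
            if where is not Where.NONE:
                raise self.error("duplicate where clause")
            where = Where(w)

        return Condition(
            subjects=tuple(subjects),
            relation=relation,
            predicates=tuple(predicates),
            subject_combinator=subj_comb or Combinator.OR,
            predicate_combinator=pred_comb or Combinator.AND,
            where=where,
        )

    def _subject_ahead(self, offset: int) -> bool:
        """Is the token at `offset` the start of a subject (vs. a predicate)?"""
        w = self.peek_word(offset)
        if w in ("atom", "alpha", "bond", "molecule"):
            # 'atom 1' is a subject; bare 'atom'/'bond' inside a predicate is not
            if w == "atom":
                nxt = self.peek(offset + 1)
                return nxt.kind == "INT" or (
                    nxt.kind == "WORD" and nxt.value.lower() in NUMBER_WORDS
                )
            return True
        t = self.peek(offset)
        return t.kind == "WORD" and w not in _RESERVED and w not in _ELEMENT_WORDS

    def parse_subject(self, scope: set[str]) -> Subject:
        w = self.peek_word()
        if w == "atom":
            self.next()
            return Subject(SubjectKind.ATOM, (self.expect_int(),))
        if w == "alpha":
            self.next()
            self.expect_word("to")
            self.expect_word("atom")
            return Subject(SubjectKind.ALPHA_TO_ATOM, (self.expect_int(),))
        if w == "bond":
            self.next()
            self.expect_word("between")
            self.expect_word("atom")
            i = self.expect_int()
            self.expect_word("and")
            self.expect_word("atom")
            j = self.expect_int()
            if i == j:
                raise self.error("bond subject needs two distinct atoms")
            return Subject(SubjectKind.BOND, (i, j))
        if w == "molecule":
            self.next()
            return Subject(SubjectKind.MOLECULE)
        t = self.peek()
        if t.kind == "WORD" and w not in _RESERVED:
            name = self.expect_identifier()
            if name not in scope:
                raise LogicScopeError(
                    f"variable {name!r} is not defined by any enclosing loop "
                    f"(line {t.line}, column {t.col})"
                )
            return Subject(SubjectKind.VARIABLE, (), name)
        raise self.error("expected a subject (atom N / alpha to atom N / "
                         "bond between atom I and atom J / molecule / variable)")

    # -- predicates -------------------------------------------------------

    def parse_predicate(self, relation: Relation) -> Predicate:
        negated = self.accept_word("not") is not None
        if relation is Relation.HAS:
            pred = self._parse_quantitative()
        else:
            pred = self._parse_qualitative()
        if negated:
            pred = Predicate(pred.kind, pred.name, pred.quantifier,
                             pred.count, pred.entity, True)
        return pred

    def _parse_quantitative(self) -> Predicate:
        if self.accept_word("at"):
            w = self.expect_word("least", "most")
            quant = Quantifier.AT_LEAST if w == "least" else Quantifier.AT_MOST
        elif self.accept_word("exactly"):
            quant = Quantifier.EXACTLY
        else:
            quant = Quantifier.EXACTLY  # bare count defaults to exact
        count = self.expect_int()
        entity = self.parse_entity()
        # tolerate the conversational trailing 'attached to it'
        if self.peek_word() == "attached" and self.peek_word(1) == "to" \
                and self.peek_word(2) == "it":
            self.next(); self.next(); self.next()
        return Predicate(PredicateKind.QUANTITATIVE, quantifier=quant,
                         count=count, entity=entity)

    def _parse_qualitative(self) -> Predicate:
        # 'the origin of <name> group'
        save = self.pos
        self.accept_word("the")
        if self.accept_word("origin"):
            self.expect_word("of")
            name = self.expect_identifier()
            self.expect_word("group")
            return Predicate(PredicateKind.GROUP_ORIGIN, name=name)
        self.pos = save

        # multi-word qualitative phrases, longest match first
        for phrase, canonical in sorted(QUALITATIVE_PHRASES.items(),
                                        key=lambda kv: -len(kv[0])):
            if all(self.peek_word(i) == w for i, w in enumerate(phrase)):
                for _ in phrase:
                    self.next()
                return Predicate(PredicateKind.QUALITATIVE, name=canonical)

        # element test: 'carbon atom' / 'carbon'
        w = self.peek_word()
        if w in _ELEMENT_WORDS:
            self.next()
            self.accept_word("atom", "atoms")
            return Predicate(PredicateKind.QUALITATIVE,
                             name=f"{_ELEMENT_WORDS[w]} atom")
        raise self.error("unknown qualitative predicate")

    def parse_entity(self) -> EntityDesc:
        w = self.peek_word()
        if w is None:
            raise self.error("expected an entity descriptor")
        if w in _plural_forms("hydrogen"):
            self.next()
            self.accept_word("atom", "atoms")
            return EntityDesc(EntityKind.HYDROGEN)
        if w in ("positive", "negative"):
            self.next()
            self.expect_word("charge", "charges")
            kind = (EntityKind.POSITIVE_CHARGE if w == "positive"
                    else EntityKind.NEGATIVE_CHARGE)
            return EntityDesc(kind)
        if w in _ELEMENT_WORDS:
            self.next()
            self.accept_word("atom", "atoms")
            return EntityDesc(EntityKind.ELEMENT, _ELEMENT_WORDS[w])
        if w in _ENTITY_SIMPLE:
            self.next()
            return _ENTITY_SIMPLE[w]
        if w not in _RESERVED:
            # '<name> group'
            if self.peek_word(1) in ("group", "groups"):
                name = self.expect_identifier()
                self.next()
                return EntityDesc(EntityKind.GROUP, name)
        raise self.error("unknown entity descriptor")

    # -- actions ----------------------------------------------------------

    def parse_action(self) -> Action:
        w = self.peek_word()
        if w == "kill":
            self.next()
            return Action(ActionKind.KILL)
        if w in ("raise", "lower"):
            self.next()
            self.expect_word("rating")
            mag = self.expect_word("slightly", "moderately", "strongly", "severely")
            return Action(ActionKind.ADJUST_RATING,
                          direction=Direction(w), magnitude=Magnitude(mag))
        if w == "ghost":
            self.next()
            t = self.peek()
            if t.kind != "STRING":
                raise self.error('expected a quoted SMILES after "ghost"')
            self.next()
            return Action(ActionKind.GHOST, ghost_fragment=t.value)
        raise self.error("expected an action (kill / raise rating ... / "
                         "lower rating ... / ghost \"...\")")

    # -- loops & sets -----------------------------------------------------

    def parse_loop(self, scope: set[str]) -> Loop:
        if self.accept_word("foreach") is None:
            self.expect_word("for")
            self.expect_word("each")
        iterand = self.parse_entity()
        where = Where.NONE
        w = self.accept_word("offpath", "onpath")
        if w:
            where = Where(w)
        self.expect_word("defined")
        self.expect_word("as")
        var = self.expect_identifier()
        if var in scope:
            raise LogicScopeError(f"variable {var!r} shadows an enclosing loop variable")
        self.expect_word("in")
        cw = self.peek_word()
        container_name = None
        if cw == "molecule":
            self.next()
            container = Container.MOLECULE
        elif cw == "rings":
            self.next()
            container = Container.RINGS
        else:
            container_name = self.expect_identifier()
            container = Container.NAMED_SET
        if self.peek().kind != "LBRACE":
            raise self.error("expected '{' to open the loop body")
        self.next()
        body = self.parse_program(scope | {var})
        if self.peek().kind != "RBRACE":
            raise self.error("expected '}' to close the loop body")
        self.next()
        return Loop(iterand, where, var, container, body, container_name)

    def parse_named_set(self, scope: set[str]) -> NamedSetDef:
        self.expect_word("set")
        name = self.expect_identifier()
        self.expect_word("as")
        entity = self.parse_entity()
        where = Where.NONE
        w = self.accept_word("offpath", "onpath")
        if w:
            where = Where(w)
        self.expect_word("in")
        self.expect_word("molecule")
        scope.add(name)
        return NamedSetDef(name, entity, where)


def parse_program(text: str) -> LogicProgram:
    """Parse logic source into a :class:`LogicProgram`.

    Raises :class:`LogicSyntaxError` / :class:`LogicScopeError` /
    :class:`LogicLexError` with line/column context.
    """
    parser = _Parser(tokenize(text))
    program = parser.parse_program()
    if parser.peek().kind == "RBRACE":
        raise parser.error("unmatched '}'")
    _check_named_set_refs(program, set())
    return program


def _check_named_set_refs(program: LogicProgram, known_sets: set[str]) -> None:
    for item in program.items:
        if isinstance(item, NamedSetDef):
            known_sets.add(item.name)
        elif isinstance(item, Loop):
            if item.container is Container.NAMED_SET \
                    and item.container_name not in known_sets:
                raise LogicScopeError(
                    f"loop iterates unknown set {item.container_name!r}")
            _check_named_set_refs(item.body, known_sets)


# ---------------------------------------------------------------------------
# serializer (canonical form: one item per line, lowercase keywords)


def _entity_text(e: EntityDesc, count: int = 1) -> str:
    plural = count != 1
    if e.kind is EntityKind.ELEMENT:
        return e.name + ("s" if plural else "")
    if e.kind is EntityKind.GROUP:
        return f"{e.name} group" + ("s" if plural else "")
    if e.kind is EntityKind.HYDROGEN:
        return "hydrogens" if plural else "hydrogen"
    if e.kind is EntityKind.POSITIVE_CHARGE:
        return "positive charges" if plural else "positive charge"
    if e.kind is EntityKind.NEGATIVE_CHARGE:
        return "negative charges" if plural else "negative charge"
    base = e.kind.value  # ring / bond / atom / heteroatom
    return base + ("s" if plural else "")


def _iterand_text(e: EntityDesc) -> str:
    if e.kind is EntityKind.ELEMENT:
        return f"{e.name} atom"
    return _entity_text(e, 1)


def _subject_text(s: Subject) -> str:
    if s.kind is SubjectKind.ATOM:
        return f"atom {s.atom_refs[0]}"
    if s.kind is SubjectKind.ALPHA_TO_ATOM:
        return f"alpha to atom {s.atom_refs[0]}"
    if s.kind is SubjectKind.BOND:
        return f"bond between atom {s.atom_refs[0]} and atom {s.atom_refs[1]}"
    if s.kind is SubjectKind.MOLECULE:
        return "molecule"
    return s.var_name


def _predicate_text(p: Predicate) -> str:
    parts = ["not "] if p.negated else []
    if p.kind is PredicateKind.GROUP_ORIGIN:
        parts.append(f"the origin of {p.name} group")
    elif p.kind is PredicateKind.QUALITATIVE:
        parts.append(p.name)
    else:
        if p.quantifier is Quantifier.AT_LEAST:
            parts.append("at least ")
        elif p.quantifier is Quantifier.AT_MOST:
            parts.append("at most ")
        parts.append(f"{p.count} {_entity_text(p.entity, p.count)}")
    return "".join(parts)


def _condition_text(c: Condition) -> str:
    subj = f" {c.subject_combinator.value} ".join(_subject_text(s) for s in c.subjects)
    rel = "is" if c.relation is Relation.IS else "has"
    preds = f" {c.predicate_combinator.value} ".join(
        _predicate_text(p) for p in c.predicates)
    out = f"{subj} {rel} {preds}"
    if c.where is not Where.NONE:
        out += f" {c.where.value}"
    return out


def _action_text(a: Action) -> str:
    if a.kind is ActionKind.KILL:
        return "kill"
    if a.kind is ActionKind.GHOST:
        return f'ghost "{a.ghost_fragment}"'
    return f"{a.direction.value} rating {a.magnitude.value}"


def _statement_text(st: Statement) -> str:
    parts = []
    for comb, cond in st.clauses:
        parts.append(f"{comb.value} {_condition_text(cond)}")
    return " ".join(parts) + f" then {_action_text(st.action)}"


def _serialize_items(items, lines: list[str]) -> None:
    for item in items:
        if isinstance(item, Statement):
            lines.append(_statement_text(item))
        elif isinstance(item, NamedSetDef):
            where = f" {item.where.value}" if item.where is not Where.NONE else ""
            lines.append(f"set {item.name} as {_iterand_text(item.entity)}"
                         f"{where} in molecule")
        elif isinstance(item, Loop):
            where = f" {item.where.value}" if item.where is not Where.NONE else ""
            if item.container is Container.MOLECULE:
                cont = "molecule"
            elif item.container is Container.RINGS:
                cont = "rings"
            else:
                cont = item.container_name
            lines.append(f"foreach {_iterand_text(item.iterand)}{where} "
                         f"defined as {item.var_name} in {cont} {{")
            _serialize_items(item.body.items, lines)
            lines.append("}")
        else:  # pragma: no cover
            raise TypeError(f"unknown program item {item!r}")


def serialize_program(program: LogicProgram) -> str:
    """Render a program in canonical text form.

    ``parse_program(serialize_program(p))`` is structurally equal to ``p``
    for every valid program; serializing an already-canonical text is a
    fixpoint.
    """
    lines: list[str] = []
    _serialize_items(program.items, lines)
    return "\n".join(lines)
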