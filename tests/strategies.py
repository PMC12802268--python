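"""Hypothesis strategies drawing random logic ASTs from the type grammar."""

from hypothesis import strategies as st

from rxnforge.logic_lang import (
    Action, ActionKind, ClauseCombinator, Combinator, Condition, Container,
    Direction, EntityDesc, EntityKind, Loop, LogicProgram, Magnitude,
    Predicate, PredicateKind, Quantifier, Relation, Statement, Subject,
    SubjectKind, Where,
)

MAP_INDICES = st.integers(min_value=1, max_value=4)
ELEMENT_NAMES = st.sampled_from(
    ["carbon", "nitrogen", "oxygen", "chlorine", "bromine", "iodine", "sulfur"])
GROUP_NAMES = st.sampled_from(["amine1", "amine2", "carboxylic_acid",
                               "boronic_acid", "terminal_alkyne"])
QUAL_NAMES = st.sampled_from(
    ["aromatic", "aliphatic", "in ring", "charged", "positively charged",
     "negatively charged", "halogen", "heteroatom", "primary center",
     "secondary center", "carbon atom", "nitrogen atom", "iodine atom"])
VAR_NAMES = st.sampled_from(["x_atom", "probe", "site_a"])


def subjects(allowed_vars=()):
    opts = [
        st.builds(lambda n: Subject(SubjectKind.ATOM, (n,)), MAP_INDICES),
        st.builds(lambda n: Subject(SubjectKind.ALPHA_TO_ATOM, (n,)), MAP_INDICES),
        st.builds(
            lambda i, j: Subject(SubjectKind.BOND, (i, j)),
            MAP_INDICES,
            MAP_INDICES.map(lambda x: x + 4),
        ),
        st.just(Subject(SubjectKind.MOLECULE)),
    ]
    if allowed_vars:
        opts.append(st.sampled_from(list(allowed_vars)).map(
            lambda v: Subject(SubjectKind.VARIABLE, (), v)))
    return st.one_of(opts)


entities = st.one_of(
    st.builds(lambda n: EntityDesc(EntityKind.ELEMENT, n), ELEMENT_NAMES),
    st.just(EntityDesc(EntityKind.HETEROATOM)),
    st.just(EntityDesc(EntityKind.HYDROGEN)),
    st.just(EntityDesc(EntityKind.POSITIVE_CHARGE)),
    st.just(EntityDesc(EntityKind.NEGATIVE_CHARGE)),
    st.just(EntityDesc(EntityKind.RING)),
    st.builds(lambda n: EntityDesc(EntityKind.GROUP, n), GROUP_NAMES),
)

qualitative_predicates = st.builds(
    lambda name, neg: Predicate(PredicateKind.QUALITATIVE, name=name, negated=neg),
    QUAL_NAMES, st.booleans())

group_predicates = st.builds(
    lambda name, neg: Predicate(PredicateKind.GROUP_ORIGIN, name=name, negated=neg),
    GROUP_NAMES, st.booleans())

quantitative_predicates = st.builds(
    lambda q, c, e, neg: Predicate(PredicateKind.QUANTITATIVE, quantifier=q,
                                   count=c, entity=e, negated=neg),
    st.sampled_from(list(Quantifier)),
    st.integers(min_value=0, max_value=9),
    entities,
    st.booleans())


def conditions(allowed_vars=()):
    def build(subs, comb, rel_preds, pred_comb, where):
        rel, preds = rel_preds
        return Condition(tuple(subs), rel, tuple(preds), comb, pred_comb, where)

    rel_preds = st.one_of(
        st.tuples(st.just(Relation.IS),
                  st.lists(st.one_of(qualitative_predicates, group_predicates),
                           min_size=1, max_size=3)),
        st.tuples(st.just(Relation.HAS),
                  st.lists(quantitative_predicates, min_size=1, max_size=3)),
    )
    return st.builds(
        build,
        st.lists(subjects(allowed_vars), min_size=1, max_size=3),
        st.sampled_from(list(Combinator)),
        rel_preds,
        st.sampled_from(list(Combinator)),
        st.sampled_from(list(Where)),
    )


actions = st.one_of(
    st.just(Action(ActionKind.KILL)),
    st.builds(lambda d, m: Action(ActionKind.ADJUST_RATING, direction=d, magnitude=m),
              st.sampled_from(list(Direction)),
              st.sampled_from(list(Magnitude))),
    st.builds(lambda s: Action(ActionKind.GHOST, ghost_fragment=s),
              st.sampled_from(["O", "Cl", "N", "O=C=O"])),
)


def statements(allowed_vars=()):
    def build(first, rest, action):
        clauses = [(ClauseCombinator.FIRST, first)]
        clauses += [(comb, cond) for comb, cond in rest]
        return Statement(tuple(clauses), action)

    return st.builds(
        build,
        conditions(allowed_vars),
        st.lists(st.tuples(
            st.sampled_from([ClauseCombinator.AND_IF, ClauseCombinator.OR_IF]),
            conditions(allowed_vars)), max_size=2),
        actions)


def loops(allowed_vars=(), depth=1):
    var = "loop_var" if not allowed_vars else f"loop_var{len(allowed_vars)}"
    inner_vars = tuple(allowed_vars) + (var,)
    body_items = st.lists(
        statements(inner_vars) if depth <= 0 else
        st.one_of(statements(inner_vars), loops(inner_vars, depth - 1)),
        min_size=1, max_size=2)
    iterands = st.one_of(
        st.builds(lambda n: EntityDesc(EntityKind.ELEMENT, n), ELEMENT_NAMES),
        st.just(EntityDesc(EntityKind.HETEROATOM)),
        st.just(EntityDesc(EntityKind.ATOM)),
        st.just(EntityDesc(EntityKind.BOND)),
        st.just(EntityDesc(EntityKind.RING)),
    )
    return st.builds(
        lambda it, where, items, cont: Loop(
            it, where, var, cont, LogicProgram(tuple(items)),
            None if cont is not Container.NAMED_SET else None),
        iterands,
        st.sampled_from(list(Where)),
        body_items,
        st.sampled_from([Container.MOLECULE, Container.RINGS]),
    )


programs = st.builds(
    lambda items: LogicProgram(tuple(items)),
    st.lists(st.one_of(statements(), loops()), max_size=4))


# ---------------------------------------------------------------------------
# eval-safe strategies: programs guaranteed evaluable against a binding of
# the pattern "[c:1][I:2]" (maps 1 and 2, bonded), with a group library.

_ATOM_QUALS = st.sampled_from(
    ["aromatic", "aliphatic", "in ring", "charged", "halogen", "heteroatom",
     "carbon atom", "nitrogen atom", "iodine atom", "primary center"])
_BOND_QUALS = st.sampled_from(
    ["aromatic", "aliphatic", "in ring", "single bond", "double bond"])
_ATOM_ENTITIES = st.one_of(
    st.builds(lambda n: EntityDesc(EntityKind.ELEMENT, n), ELEMENT_NAMES),
    st.just(EntityDesc(EntityKind.HETEROATOM)),
    st.just(EntityDesc(EntityKind.HYDROGEN)),
    st.just(EntityDesc(EntityKind.POSITIVE_CHARGE)),
    st.just(EntityDesc(EntityKind.RING)),
    st.just(EntityDesc(EntityKind.ATOM)),
    st.builds(lambda n: EntityDesc(EntityKind.GROUP, n), GROUP_NAMES),
)

_atom_subjects = st.sampled_from([
    Subject(SubjectKind.ATOM, (1,)),
    Subject(SubjectKind.ATOM, (2,)),
    Subject(SubjectKind.ALPHA_TO_ATOM, (1,)),
])


def _qual_pred(name, neg):
    return Predicate(PredicateKind.QUALITATIVE, name=name, negated=neg)


def _quant_pred(q, c, e, neg):
    return Predicate(PredicateKind.QUANTITATIVE, quantifier=q, count=c,
                     entity=e, negated=neg)


_eval_quant = st.builds(_quant_pred, st.sampled_from(list(Quantifier)),
                        st.integers(min_value=0, max_value=6),
                        _ATOM_ENTITIES, st.booleans())


def _mk_cond(subs, comb, rel, preds, pcomb, where):
    return Condition(tuple(subs), rel, tuple(preds), comb, pcomb, where)


eval_conditions = st.one_of(
    # atoms, qualitative
    st.builds(_mk_cond,
              st.lists(_atom_subjects, min_size=1, max_size=2),
              st.sampled_from(list(Combinator)),
              st.just(Relation.IS),
              st.lists(st.one_of(
                  st.builds(_qual_pred, _ATOM_QUALS, st.booleans()),
                  st.builds(lambda n, neg: Predicate(
                      PredicateKind.GROUP_ORIGIN, name=n, negated=neg),
                      GROUP_NAMES, st.booleans())),
                  min_size=1, max_size=2),
              st.sampled_from(list(Combinator)),
              st.sampled_from(list(Where))),
    # atoms, quantitative
    st.builds(_mk_cond,
              st.lists(_atom_subjects, min_size=1, max_size=2),
              st.sampled_from(list(Combinator)),
              st.just(Relation.HAS),
              st.lists(_eval_quant, min_size=1, max_size=2),
              st.sampled_from(list(Combinator)),
              st.sampled_from(list(Where))),
    # whole molecule, quantitative only
    st.builds(_mk_cond,
              st.just((Subject(SubjectKind.MOLECULE),)),
              st.just(Combinator.OR),
              st.just(Relation.HAS),
              st.lists(_eval_quant, min_size=1, max_size=2),
              st.sampled_from(list(Combinator)),
              st.just(Where.NONE)),
    # the mapped bond, qualitative
    st.builds(_mk_cond,
              st.just((Subject(SubjectKind.BOND, (1, 2)),)),
              st.just(Combinator.OR),
              st.just(Relation.IS),
              st.lists(st.builds(_qual_pred, _BOND_QUALS, st.booleans()),
                       min_size=1, max_size=2),
              st.sampled_from(list(Combinator)),
              st.sampled_from(list(Where))),
)


def eval_statements(extra_vars=()):
    conds = eval_conditions
    if extra_vars:
        var_conds = st.builds(
            _mk_cond,
            st.sampled_from([
                (Subject(SubjectKind.VARIABLE, (), v),) for v in extra_vars]),
            st.just(Combinator.OR),
            st.just(Relation.IS),
            st.lists(st.builds(_qual_pred, _ATOM_QUALS, st.booleans()),
                     min_size=1, max_size=2),
            st.sampled_from(list(Combinator)),
            st.sampled_from(list(Where)))
        conds = st.one_of(conds, var_conds)

    def build(first, rest, action):
        clauses = [(ClauseCombinator.FIRST, first)] + list(rest)
        return Statement(tuple(clauses), action)

    return st.builds(
        build, conds,
        st.lists(st.tuples(
            st.sampled_from([ClauseCombinator.AND_IF, ClauseCombinator.OR_IF]),
            conds), max_size=2),
        actions)


_eval_loops = st.builds(
    lambda it, where, items: Loop(
        it, where, "loop_atom", Container.MOLECULE, LogicProgram(tuple(items))),
    st.one_of(
        st.builds(lambda n: EntityDesc(EntityKind.ELEMENT, n), ELEMENT_NAMES),
        st.just(EntityDesc(EntityKind.HETEROATOM)),
        st.just(EntityDesc(EntityKind.ATOM))),
    st.sampled_from(list(Where)),
    st.lists(eval_statements(("loop_atom",)), min_size=1, max_size=2))

eval_programs = st.builds(
    lambda items: LogicProgram(tuple(items)),
    st.lists(st.one_of(eval_statements(), _eval_loops), max_size=5))
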