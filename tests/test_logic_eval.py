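import itertools

import pytest
from hypothesis import given, settings
from rdkit import Chem

from rxnforge.logic_eval import (
    AtomObj, BondObj, EvalEnv, LogicEvalError, LogicOutcome, LogicTypeError,
    MAGNITUDE_STEPS, MolObj, Rating, eval_condition, eval_subject,
    run_program, run_statement,
)
from rxnforge.logic_lang import (
    Direction, Magnitude, Where, parse_program,
)
from rxnforge.pattern_engine import compile_pattern, find_matches

from .strategies import eval_programs


def binding_for(smiles, smarts, index=0):
    mol = Chem.MolFromSmiles(smiles)
    matches = find_matches(compile_pattern(smarts), mol)
    return matches[index]


def first_condition(text):
    return parse_program(text).items[0].clauses[0][1]


def first_statement(text):
    return parse_program(text).items[0]


@pytest.fixture(scope="module")
def iodobenzene_binding():
    return binding_for("Ic1ccccc1", "[c:1][I:2]")


class TestEvalSubject:
    def test_atom_maps_to_bound_index(self, iodobenzene_binding):
        b = iodobenzene_binding
        subj = first_condition("if atom 1 is aromatic then kill").subjects[0]
        assert eval_subject(subj, b) == [AtomObj(b.atom_map[1])]

    def test_alpha_to_ipso_carbon(self, iodobenzene_binding):
        # ipso carbon of iodobenzene: iodine + two ortho carbons
        b = iodobenzene_binding
        subj = first_condition("if alpha to atom 1 is aromatic then kill").subjects[0]
        objs = eval_subject(subj, b)
        assert len(objs) == 3
        elements = sorted(b.mol.GetAtomWithIdx(o.idx).GetAtomicNum() for o in objs)
        assert elements == [6, 6, 53]

    def test_alpha_offpath_excludes_onpath_iodine(self, iodobenzene_binding):
        b = iodobenzene_binding
        cond = first_condition("if alpha to atom 1 offpath is aromatic then kill")
        objs = [o for o in eval_subject(cond.subjects[0], b)
                if o.idx in b.offpath_atoms]
        assert len(objs) == 2
        assert all(b.mol.GetAtomWithIdx(o.idx).GetAtomicNum() == 6 for o in objs)

    def test_bond_subject_resolves(self, iodobenzene_binding):
        b = iodobenzene_binding
        subj = first_condition(
            "if bond between atom 1 and atom 2 is aromatic then kill").subjects[0]
        (obj,) = eval_subject(subj, b)
        assert isinstance(obj, BondObj)

    def test_bond_between_unbonded_atoms_raises(self):
        b = binding_for("Ic1ccc(I)cc1", "[I:1][c][c][c][c:2]")
        subj = first_condition(
            "if bond between atom 1 and atom 2 is aromatic then kill").subjects[0]
        with pytest.raises(LogicEvalError):
            eval_subject(subj, b)

    def test_molecule_subject(self, iodobenzene_binding):
        subj = first_condition("if molecule has 1 iodine then kill").subjects[0]
        assert eval_subject(subj, iodobenzene_binding) == [MolObj()]

    def test_unbound_variable_raises(self, iodobenzene_binding):
        from rxnforge.logic_lang import Subject, SubjectKind
        subj = Subject(SubjectKind.VARIABLE, (), "ghost_var")
        with pytest.raises(LogicEvalError):
            eval_subject(subj, iodobenzene_binding, EvalEnv())


class TestEvalCondition:
    def test_aromatic_true_on_benzene_false_on_cyclohexane(self):
        cond = first_condition("if atom 1 is aromatic then kill")
        assert eval_condition(cond, binding_for("c1ccccc1", "[#6:1]")) is True
        assert eval_condition(cond, binding_for("C1CCCCC1", "[#6:1]")) is False

    def test_chlorine_counts(self):
        cond = first_condition("if atom 1 has at most 2 chlorines then kill")
        chloroform = binding_for("ClC(Cl)Cl", "[CX4:1]")
        dcm = binding_for("ClCCl", "[CX4:1]")
        assert eval_condition(cond, chloroform) is False
        assert eval_condition(cond, dcm) is True

    def test_secondary_amine_has_one_hydrogen(self):
        cond = first_condition("if atom 1 has one hydrogen then kill")
        b = binding_for("CCNCC", "[NX3:1]")
        assert eval_condition(cond, b) is True

    def test_subject_or_combination(self):
        # "atom 1 or atom 2 is X" is true if either satisfies
        b = binding_for("Ic1ccccc1", "[c:1][I:2]")
        either = first_condition("if atom 1 or atom 2 is iodine atom then kill")
        both = first_condition("if atom 1 and atom 2 is iodine atom then kill")
        assert eval_condition(either, b) is True
        assert eval_condition(both, b) is False

    def test_predicate_and_or(self):
        b = binding_for("Ic1ccccc1", "[c:1][I:2]")
        assert eval_condition(first_condition(
            "if atom 1 is carbon atom and aromatic then kill"), b) is True
        assert eval_condition(first_condition(
            "if atom 1 is iodine atom or aromatic then kill"), b) is True
        assert eval_condition(first_condition(
            "if atom 1 is iodine atom and aromatic then kill"), b) is False

    def test_where_empties_subject_set_to_false(self):
        # atom 1 is always onpath, so an offpath filter leaves nothing
        b = binding_for("Ic1ccccc1", "[c:1][I:2]")
        cond = first_condition("if atom 1 is aromatic offpath then kill")
        assert eval_condition(cond, b) is False

    def test_negation(self):
        b = binding_for("C1CCCCC1", "[#6:1]")
        assert eval_condition(first_condition(
            "if atom 1 is not aromatic then kill"), b) is True

    def test_group_origin_predicate(self, group_library):
        b = binding_for("NCc1ccccc1", "[NX3:1]")
        cond = first_condition("if atom 1 is the origin of amine1 group then kill")
        assert eval_condition(cond, b, group_library=group_library) is True

    def test_qualitative_on_molecule_is_typing_error(self):
        b = binding_for("c1ccccc1", "[#6:1]")
        cond = first_condition("if molecule has 1 ring then kill")
        from rxnforge.logic_lang import (
            Condition, Predicate, PredicateKind, Relation,
        )
        bad = Condition(cond.subjects, Relation.IS,
                        (Predicate(PredicateKind.QUALITATIVE, name="aromatic"),))
        with pytest.raises(LogicTypeError):
            eval_condition(bad, b)

    def test_molecule_counts(self):
        b = binding_for("Ic1ccc(I)cc1", "[c:1][I:2]")
        assert eval_condition(first_condition(
            "if molecule has at least 2 iodines then kill"), b) is True
        assert eval_condition(first_condition(
            "if molecule has exactly 1 ring then kill"), b) is True


class TestRunStatement:
    def test_kill_fires_when_both_true(self, iodobenzene_binding):
        st = first_statement(
            "if atom 1 is carbon atom and if atom 1 is aromatic then kill")
        out = run_statement(st, iodobenzene_binding, EvalEnv(), LogicOutcome())
        assert out.rating.killed is True
        assert out.trace == [(
            "if atom 1 is carbon atom and if atom 1 is aromatic then kill", True)]

    def test_and_short_circuit_no_change(self):
        b = binding_for("CC", "[CX4:1]")  # aliphatic carbon
        st = first_statement(
            "if atom 1 is aromatic and if atom 1 is carbon atom then kill")
        out = run_statement(st, b, EvalEnv(), LogicOutcome())
        assert out.rating.killed is False
        assert out.trace[0][1] is False

    def test_amine_lowers_to_40(self, group_library):
        # 50 - 10 (moderately) via the magnitude table
        b = binding_for("NCc1ccc(I)cc1", "[c:1][I:2]")
        st = first_statement(
            "if molecule has at least 1 amine1 group then lower rating moderately")
        out = run_statement(st, b, EvalEnv(), LogicOutcome(),
                            group_library=group_library)
        assert out.rating.value == 40
        assert out.rating.deltas == [(Direction.LOWER, Magnitude.MODERATELY, 10)]

    def test_action_fires_exactly_once_per_statement(self, iodobenzene_binding):
        st = first_statement(
            "if atom 1 is aromatic or if atom 2 is iodine atom "
            "then raise rating slightly")
        out = run_statement(st, iodobenzene_binding, EvalEnv(), LogicOutcome())
        assert len(out.rating.deltas) == 1

    @pytest.mark.parametrize("a,b", list(itertools.product([True, False], repeat=2)))
    def test_truth_table_and_if(self, a, b):
        binding = binding_for("Ic1ccccc1", "[c:1][I:2]")
        # atom 1 is an aromatic carbon: 'aromatic' True, 'iodine atom' False
        ca = "atom 1 is aromatic" if a else "atom 1 is iodine atom"
        cb = "atom 1 is aromatic" if b else "atom 1 is iodine atom"
        st = first_statement(f"if {ca} and if {cb} then kill")
        out = run_statement(st, binding, EvalEnv(), LogicOutcome())
        assert out.rating.killed is (a and b)

    @pytest.mark.parametrize("a,b", list(itertools.product([True, False], repeat=2)))
    def test_truth_table_or_if(self, a, b):
        binding = binding_for("Ic1ccccc1", "[c:1][I:2]")
        ca = "atom 1 is aromatic" if a else "atom 1 is iodine atom"
        cb = "atom 1 is aromatic" if b else "atom 1 is iodine atom"
        st = first_statement(f"if {ca} or if {cb} then kill")
        out = run_statement(st, binding, EvalEnv(), LogicOutcome())
        assert out.rating.killed is (a or b)


TOLUENE_LOOP = """\
foreach carbon atom offpath defined as carbon_atom in molecule {
if carbon_atom is aromatic then raise rating slightly
}
"""


class TestRunLoop:
    def test_toluene_walkthrough_six_raises_final_80(self):
        b = binding_for("Cc1ccccc1", "[CH3:1]")
        out = run_program(parse_program(TOLUENE_LOOP), b)
        assert len(out.rating.deltas) == 6
        assert all(d == (Direction.RAISE, Magnitude.SLIGHTLY, 5)
                   for d in out.rating.deltas)
        assert out.rating.value == 80
        assert len(out.trace) == 6  # one statement evaluation per iteration

    def test_ethane_one_offpath_carbon_no_delta(self):
        b = binding_for("CC", "[CH3:1]")
        out = run_program(parse_program(TOLUENE_LOOP), b)
        assert len(out.trace) == 1
        assert out.rating.deltas == []
        assert out.rating.value == 50

    def test_empty_iteration_runs_nothing(self):
        b = binding_for("CC", "[CH3:1]")
        prog = parse_program(
            "foreach nitrogen atom defined as n in molecule "
            "{ if n is aromatic then kill }")
        out = run_program(prog, b)
        assert out.trace == []
        assert out.rating.value == 50

    @pytest.mark.parametrize("descriptor,counter", [
        ("carbon atom", lambda m: sum(1 for a in m.GetAtoms()
                                      if a.GetAtomicNum() == 6)),
        ("nitrogen atom", lambda m: sum(1 for a in m.GetAtoms()
                                        if a.GetAtomicNum() == 7)),
        ("heteroatom", lambda m: sum(1 for a in m.GetAtoms()
                                     if a.GetAtomicNum() not in (1, 6))),
        ("atom", lambda m: m.GetNumAtoms()),
        ("bond", lambda m: m.GetNumBonds()),
    ])
    def test_loop_count_law(self, panel, descriptor, counter):
        """Body executions equal the brute-force object count (where=NONE,
        single whole-molecule binding)."""
        prog = parse_program(
            f"foreach {descriptor} defined as x in molecule "
            "{ if x is not aromatic then raise rating slightly }")
        pattern = compile_pattern("[*:1]")
        for mol in panel[:20]:
            bindings = find_matches(pattern, mol)
            out = run_program(prog, bindings[0])
            assert len(out.trace) == counter(mol), Chem.MolToSmiles(mol)

    def test_offpath_filter_in_loop_count(self):
        b = binding_for("Cc1ccccc1", "[CH3:1]")
        prog = parse_program(
            "foreach carbon atom offpath defined as c in molecule "
            "{ if c is carbon atom then raise rating slightly }")
        assert len(run_program(prog, b).trace) == 6

    def test_named_set_collected_then_iterated(self):
        b = binding_for("Cc1ccccc1", "[CH3:1]")
        prog = parse_program(
            "set ring_carbons as carbon atom offpath in molecule\n"
            "foreach carbon atom defined as c in ring_carbons "
            "{ if c is aromatic then raise rating slightly }")
        out = run_program(prog, b)
        assert len(out.rating.deltas) == 6

    def test_ring_loop(self):
        b = binding_for("c1ccc2ccccc2c1", "[c:1]")
        prog = parse_program(
            "foreach ring defined as r in rings "
            "{ if r is aromatic then raise rating slightly }")
        out = run_program(prog, b)
        assert len(out.rating.deltas) == 2  # naphthalene: two SSSR rings


class TestRunProgram:
    def test_empty_program(self, iodobenzene_binding):
        out = run_program(parse_program(""), iodobenzene_binding)
        assert out.rating.value == 50
        assert out.rating.killed is False
        assert out.ghosts == []

    def test_kill_is_monotone_over_later_raises(self, iodobenzene_binding):
        prog = parse_program(
            "if atom 1 is aromatic then kill\n"
            "if atom 1 is aromatic then raise rating severely")
        out = run_program(prog, iodobenzene_binding)
        assert out.rating.killed is True

    def test_magnitude_arithmetic(self, iodobenzene_binding):
        prog = parse_program(
            "if atom 1 is aromatic then raise rating slightly\n"
            "if atom 2 is iodine atom then lower rating strongly")
        out = run_program(prog, iodobenzene_binding)
        assert out.rating.value == 50 + 5 - 20

    def test_ghost_action_recorded(self, iodobenzene_binding):
        prog = parse_program('if atom 1 is aromatic then ghost "O"')
        out = run_program(prog, iodobenzene_binding)
        assert out.ghosts == ["O"]

    def test_magnitude_table(self):
        assert MAGNITUDE_STEPS == {
            Magnitude.SLIGHTLY: 5, Magnitude.MODERATELY: 10,
            Magnitude.STRONGLY: 20, Magnitude.SEVERELY: 35}


class TestRatingAlgebra:
    def test_clamp_low(self):
        r = Rating()
        for _ in range(5):
            r.adjust(Direction.LOWER, Magnitude.SEVERELY)
        assert r.value == 0

    def test_clamp_high(self):
        r = Rating()
        for _ in range(5):
            r.adjust(Direction.RAISE, Magnitude.SEVERELY)
        assert r.value == 100

    def test_retained_boundary(self):
        r = Rating()
        r.adjust(Direction.LOWER, Magnitude.STRONGLY)
        r.adjust(Direction.LOWER, Magnitude.STRONGLY)
        r.adjust(Direction.LOWER, Magnitude.MODERATELY)
        assert r.value == 0
        assert r.retained is False  # zero is not positive

    @settings(max_examples=400, deadline=None)
    @given(eval_programs)
    def test_clamping_random_programs(self, program):
        b = binding_for("Ic1ccccc1", "[c:1][I:2]")
        out = run_program(program, b, _SHARED_LIB)
        assert 0 <= out.rating.value <= 100

    @settings(max_examples=300, deadline=None)
    @given(eval_programs)
    def test_raise_monotonicity(self, program):
        """Appending an always-firing raise never lowers the final rating."""
        b = binding_for("Ic1ccccc1", "[c:1][I:2]")
        before = run_program(program, b, _SHARED_LIB).rating
        raised = parse_program(serialize_or_empty(program)
                               + "\nif molecule has at least 0 atoms "
                                 "then raise rating slightly")
        after = run_program(raised, b, _SHARED_LIB).rating
        assert after.value >= before.value or before.killed

    @settings(max_examples=300, deadline=None)
    @given(eval_programs)
    def test_kill_monotonicity(self, program):
        """Appending an always-firing kill never increases survivors."""
        b = binding_for("Ic1ccccc1", "[c:1][I:2]")
        before = run_program(program, b, _SHARED_LIB).rating
        killed = parse_program(serialize_or_empty(program)
                               + "\nif molecule has at least 0 atoms then kill")
        after = run_program(killed, b, _SHARED_LIB).rating
        assert after.retained is False
        assert int(after.retained) <= int(before.retained)


from rxnforge.logic_lang import serialize_program as _ser
from rxnforge.pattern_engine import GroupLibrary as _GL

_SHARED_LIB = _GL.default()


def serialize_or_empty(program):
    text = _ser(program)
    return text if text else ""
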