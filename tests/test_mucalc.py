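import numpy as np
import pytest

from radiomodal import (
    BoxAll,
    Diamond,
    DiamondComplement,
    FF,
    Min,
    Or,
    ParseError,
    PropRef,
    PropertyError,
    PropertySet,
    TT,
    Var,
    chain_lts,
    check_patient,
    localize,
    parse_formula,
    parse_properties,
    property_sat_sets,
    satisfying_states,
    diagnosis_properties,
    write_properties,
)
from radiomodal.mucalc import DIAGNOSIS_PROPERTY_TEXT, _Evaluator
from conftest import sequence_from_levels
from oracles import (
    adjacency,
    bf_eval,
    bf_eval_enum,
    random_chain_actions,
    random_formula,
    suffix_scan,
)


class TestParsing:
    def test_bundled_property_set(self, props):
        assert props.names == ("F0", "F1", "F2", "F3", "F4", "F10", "F11", "F12", "F13", "F14")
        assert props.entry == "F0"
        assert props["F0"] == Or(PropRef("F1"), PropRef("F10"))

    def test_f3_recursion_exclusion_set(self, props):
        f3 = props["F3"]
        assert isinstance(f3, Min)
        recursion = f3.body.right
        assert isinstance(recursion, DiamondComplement)
        assert recursion.excluded == frozenset({"b3of3sphericity", "b1of3kurtosis"})

    def test_f14_terminal_structure(self, props):
        f14 = props["F14"]
        terminal = f14.body.left
        assert terminal == Diamond(
            frozenset({"b2of3meshsurface", "b2of3elongation"}), BoxAll(FF())
        )
        assert f14.body.right == DiamondComplement(frozenset(), Var("X"))

    def test_simple_min_formula_ast(self):
        defs = parse_properties("prop P = (min X = <a> tt \\/ <->X)", entry="P")
        assert defs["P"] == Min(
            "X", Or(Diamond(frozenset({"a"}), TT()), DiamondComplement(frozenset(), Var("X")))
        )

    def test_unicode_typography_accepted(self):
        ascii_defs = parse_properties(
            "prop F1 = (min x = <a><b> F2 \\/ <->X)\nprop F2 = tt", entry="F1"
        )
        unicode_defs = parse_properties(
            "prop F1 = (min x = < a>< b> F2 ∨ < − > X)\nprop F2 = tt", entry="F1"
        )
        assert ascii_defs.definitions == unicode_defs.definitions

    def test_case_insensitive_fixpoint_variable(self):
        defs = parse_properties("prop P = (min x = <a> tt \\/ <-> X)", entry="P")
        body = defs["P"]
        assert body.var == "x"
        assert body.body.right == DiamondComplement(frozenset(), Var("x"))

    def test_cyclic_references_rejected(self):
        with pytest.raises(PropertyError, match="cyclic"):
            parse_properties("prop A = B\nprop B = A", entry="A")

    def test_undefined_reference_rejected(self):
        with pytest.raises(PropertyError, match="undefined"):
            parse_properties("prop A = (min X = <a> Y \\/ <->X)", entry="A")

    def test_duplicate_definition_rejected(self):
        with pytest.raises(ParseError, match="duplicate"):
            parse_properties("prop A = tt\nprop A = ff")

    def test_greatest_fixpoint_unsupported(self):
        with pytest.raises(ParseError, match="unsupported"):
            parse_formula("(max X = <a> tt \\/ <->X)")

    def test_conjunction_unsupported(self):
        with pytest.raises(ParseError, match="unsupported"):
            parse_formula("tt /\\ tt")

    def test_empty_diamond_rejected(self):
        with pytest.raises(ParseError, match="empty action set"):
            parse_formula("<> tt")

    def test_bundled_properties_round_trip_through_serializer(self, props):
        again = parse_properties(write_properties(props), entry="F0")
        assert again.definitions == props.definitions


class TestSemantics:
    def test_box_ff_characterizes_deadlock(self):
        lts = chain_lts(["a", "b"], actions_per_slice=None)
        assert satisfying_states(lts, BoxAll(FF())) == frozenset({2})

    def test_two_step_fixpoint_by_hand(self):
        # min X = <a><b>tt \/ <->X on the chain a.b.nil holds at 0 (direct
        # match) and nowhere else (no suffix matches from 1 or 2)
        lts = chain_lts(["a", "b"], actions_per_slice=None)
        f = Min(
            "X",
            Or(
                Diamond(frozenset({"a"}), Diamond(frozenset({"b"}), TT())),
                DiamondComplement(frozenset(), Var("X")),
            ),
        )
        assert satisfying_states(lts, f) == frozenset({0})

    def test_matches_subset_enumeration_oracle_on_tiny_chains(self):
        rng = np.random.default_rng(2024)
        alphabet = ["a", "b", "c"]
        for _ in range(150):
            actions = random_chain_actions(rng, 5, alphabet)
            lts = chain_lts(actions, actions_per_slice=None)
            f = random_formula(rng, depth=3, alphabet=alphabet)
            succ, n = adjacency(lts)
            assert set(satisfying_states(lts, f)) == bf_eval_enum(succ, n, f, {})

    def test_monotone_fixpoint_stages(self):
        rng = np.random.default_rng(7)
        alphabet = ["a", "b"]
        for _ in range(50):
            actions = random_chain_actions(rng, 12, alphabet)
            lts = chain_lts(actions, actions_per_slice=None)
            f = random_formula(rng, depth=4, alphabet=alphabet)
            if not isinstance(f, Min):
                f = Min("Z", Or(f, DiamondComplement(frozenset(), Var("Z"))))
            stages = _Evaluator(lts, None).min_stages(f, {})
            for early, late in zip(stages, stages[1:]):
                assert early <= late
            assert len(stages) <= lts.n_states + 1

    def test_suffix_scan_equivalence_on_chains(self):
        rng = np.random.default_rng(99)
        alphabet = ["a", "b", "c"]
        for _ in range(100):
            actions = random_chain_actions(rng, 15, alphabet)
            lts = chain_lts(actions, actions_per_slice=None)
            phi = random_formula(rng, depth=2, alphabet=alphabet)
            eventually = Min("S", Or(phi, DiamondComplement(frozenset(), Var("S"))))
            direct = set(satisfying_states(lts, eventually))
            phi_states = set(satisfying_states(lts, phi))
            assert direct == suffix_scan(actions, phi_states)


class TestCheckPatient:
    def test_four_pairs_satisfy_via_f1(self, props, satisfier_levels, make_sequence):
        from radiomodal import build_process, to_lts

        lts = to_lts(build_process(make_sequence("p", satisfier_levels)))
        result = check_patient(lts, props)
        assert result.verdict is True
        assert result.witness is not None
        # on a chain every witness is a prefix of the action sequence
        chain_actions = [a for _, a, _ in lts.transitions]
        assert list(result.witness) == chain_actions[: len(result.witness)]
        assert result.witness[-2:] == ("b3of3sphericity", "b1of3kurtosis")

    def test_no_pattern_anywhere_fails_with_note(self, props, make_sequence):
        from radiomodal import build_process, to_lts

        lts = to_lts(build_process(make_sequence("p", [(2, 2, 2, 2, 1)] * 3)))
        result = check_patient(lts, props)
        assert result.verdict is False
        assert result.witness is None
        assert "F" in result.failure

    def test_empty_model_deadlock_semantics(self, props):
        lts = chain_lts([], actions_per_slice=None)
        assert satisfying_states(lts, BoxAll(FF())) == frozenset({0})
        assert 0 not in satisfying_states(lts, PropRef(props.entry), props)

    def test_padding_preserves_unrestricted_satisfaction(self, props, satisfier_levels, make_sequence):
        # calm slices inserted anywhere do not mention the pattern actions,
        # so the verdict stays true
        calm = (2, 3, 1, 2, 3)
        padded = [calm, *satisfier_levels[:3], calm, *satisfier_levels[3:], calm]
        from radiomodal import build_process, to_lts

        lts = to_lts(build_process(make_sequence("p", padded)))
        assert check_patient(lts, props).verdict is True


class TestLocalization:
    def test_entry_satisfaction_includes_slice_zero(self, props, satisfier_levels, make_sequence):
        from radiomodal import build_process, to_lts

        lts = to_lts(build_process(make_sequence("p", satisfier_levels)))
        slices = localize(lts, props, ["F0"])
        assert 0 in slices["F0"]

    def test_mid_chain_property_localizes_to_its_slice(self):
        # b1of3kurtosis occurs only in slice 1 of a 3-slice model
        seq = sequence_from_levels("p", [(2, 2, 2, 2, 2), (2, 1, 2, 2, 2), (2, 2, 2, 2, 2)])
        from radiomodal import build_process, to_lts

        lts = to_lts(build_process(seq))
        custom = parse_properties("prop Q = <b1of3kurtosis> tt", entry="Q")
        slices = localize(lts, custom, ["Q"])
        assert slices["Q"] == {1}

    def test_false_property_localizes_nowhere(self, make_sequence):
        from radiomodal import build_process, to_lts

        lts = to_lts(build_process(make_sequence("p", [(2, 2, 2, 2, 2)])))
        custom = parse_properties("prop Q = <b3of3sphericity> tt", entry="Q")
        assert localize(lts, custom, ["Q"])["Q"] == set()

    def test_unknown_name_rejected(self, props, make_sequence):
        from radiomodal import build_process, to_lts

        lts = to_lts(build_process(make_sequence("p", [(2, 2, 2, 2, 2)])))
        with pytest.raises(PropertyError, match="unknown"):
            localize(lts, props, ["F99"])


class TestBundledPropertySemantics:
    def test_requires_four_pairs(self, props, make_sequence):
        from radiomodal import build_process, to_lts

        pair, calm = (3, 1, 2, 2, 2), (2, 2, 2, 2, 2)
        for n_pairs, expected in [(3, False), (4, True), (5, True)]:
            slices = [pair] * n_pairs + [calm] * 2
            lts = to_lts(build_process(make_sequence("p", slices)))
            assert check_patient(lts, props).verdict is expected

    def test_stray_pattern_action_breaks_restricted_phase(self, props, make_sequence):
        # a lone low-kurtosis slice between the 3rd and 4th pairs blocks the
        # restricted recursion of F4 (b1of3kurtosis is excluded there)
        pair, calm = (3, 1, 2, 2, 2), (2, 2, 2, 2, 2)
        stray = (2, 1, 2, 2, 2)
        ok = [pair, pair, calm, pair, calm, pair]
        broken = [pair, pair, calm, pair, stray, pair]
        from radiomodal import build_process, to_lts

        assert check_patient(to_lts(build_process(make_sequence("p", ok))), props).verdict
        assert not check_patient(
            to_lts(build_process(make_sequence("p", broken))), props
        ).verdict

    def test_stray_before_restricted_phase_is_harmless(self, props, make_sequence):
        # unrestricted recursion in F1/F2 tolerates stray pattern actions
        pair, calm, stray = (3, 1, 2, 2, 2), (2, 2, 2, 2, 2), (2, 1, 2, 2, 2)
        slices = [stray, pair, calm, pair, pair, pair]
        from radiomodal import build_process, to_lts

        assert check_patient(to_lts(build_process(make_sequence("p", slices))), props).verdict
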