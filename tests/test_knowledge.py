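"""Declarative network loading and the production-rule machinery."""

import random

import pytest
from hypothesis import given, settings, strategies as st

from wmdec.knowledge import (LearningConfig, LoadError, ProductionRule,
                             association_rule_name, compile_condition,
                             create_association_rule, evaluate_condition,
                             load_dltm, parse_rules, select_rule,
                             update_rule_strength)


class TestLoadDltm:
    def test_sub_link_is_mirrored_by_sup(self):
        net = load_dltm("Y\nX link=SUB:Y\n")
        assert net["Y"].has_link("SUP", "X")
        assert net["X"].has_link("SUB", "Y")

    def test_opp_links_are_symmetric(self):
        net = load_dltm("B\nA link=OPP:B\n")
        assert net["B"].has_link("OPP", "A")

    def test_empty_spec_gives_empty_network(self):
        assert load_dltm("") .nodes == {}

    def test_all_strengths_are_half(self):
        net = load_dltm("A\nB link=PROP:A\n")
        assert all(n.strength == 0.50 for n in net.nodes.values())

    def test_unknown_link_target_raises_with_node_name(self):
        with pytest.raises(LoadError, match="GHOST"):
            load_dltm("A link=SUP:GHOST\n")

    def test_duplicate_node_rejected(self):
        with pytest.raises(LoadError):
            load_dltm("A\nA\n")

    def test_idempotent_under_reload(self):
        net = load_dltm("B\nA link=SUB:B link=OPP:C\nC\n")
        again = load_dltm(net.to_spec())
        for name, node in net.nodes.items():
            assert sorted(again[name].links) == sorted(node.links)


class TestRuleParsing:
    def test_printed_style_rule_round_trips(self):
        text = """
        RULE encode strength=0.95 duration=2:
          IF newcnt(ISM) == 1 AND X = isnew(ISM, 1) AND !ltmhas(X, TARGET)
          THEN mkinst(X, ANY, NOLOC)
        """
        (rule,) = parse_rules(text)
        assert rule.name == "encode"
        assert rule.strength == 0.95 and rule.duration == 2
        assert [t.function for t in rule.condition] == \
            ["newcnt", "isnew", "ltmhas"]
        assert rule.condition[1].binds == "X"
        assert rule.condition[2].negated
        assert rule.action.function == "mkinst"

    def test_variable_use_before_binding_rejected(self):
        with pytest.raises(LoadError, match="before being bound"):
            parse_rules("RULE bad strength=0.5 duration=1: "
                        "IF ltmhas(X, TARGET) THEN noop()")

    def test_duration_must_be_positive(self):
        with pytest.raises(LoadError):
            parse_rules("RULE bad strength=0.5 duration=0: "
                        "IF newcnt(ISM) == 1 THEN noop()")


def brute_force_match(rule, state, registry, symbols):
    """Independent oracle: enumerate all assignments of the rule's variables
    over `symbols` and check the condition as a plain conjunction."""
    variables = [t.binds for t in rule.condition if t.binds]
    import itertools

    for combo in itertools.product(symbols, repeat=len(variables)):
        env = dict(zip(variables, combo))

        def value_of(term):
            args = [env.get(a, a) for a in term.args]
            return registry[term.function](state, *args)

        ok = True
        for term in rule.condition:
            v = value_of(term)
            if term.comparison is not None:
                from wmdec.knowledge import _compare
                v = _compare(v, term.comparison,
                             env.get(term.compare_to, term.compare_to))
            if term.binds is not None:
                # left-to-right binding: the assignment must equal the
                # predicate's value
                if not v or v != env[term.binds]:
                    ok = False
                    break
                continue
            if bool(v) == term.negated:
                ok = False
                break
        if ok:
            return True
    return False


class TestEvaluateCondition:
    REGISTRY = {
        "present": lambda s, x: x if x in s else False,
        "linked": lambda s, x, y: (x, y) in s.get("links", ()),
        "count": lambda s: len([k for k in s if k != "links"]),
    }

    def _registry_state(self, items, links=()):
        state = {k: True for k in items}
        state["links"] = set(links)
        return state

    def test_binding_and_negation(self):
        (rule,) = parse_rules(
            "RULE r strength=0.5 duration=1: "
            "IF X = present(AA) AND !present(BB) THEN noop(X)")
        ok, b = evaluate_condition(rule, self._registry_state(["AA"]),
                                   self.REGISTRY)
        assert ok and b == {"X": "AA"}
        ok, _ = evaluate_condition(rule, self._registry_state(["AA", "BB"]),
                                   self.REGISTRY)
        assert not ok

    def test_negated_term_true_on_empty_state(self):
        (rule,) = parse_rules("RULE r strength=0.5 duration=1: "
                              "IF !present(AA) THEN noop()")
        ok, _ = evaluate_condition(rule, self._registry_state([]),
                                   self.REGISTRY)
        assert ok

    def test_count_comparison(self):
        (rule,) = parse_rules("RULE r strength=0.5 duration=1: "
                              "IF count() == 1 THEN noop()")
        assert evaluate_condition(rule, self._registry_state(["A"]),
                                  self.REGISTRY)[0]
        assert not evaluate_condition(rule, self._registry_state(["A", "B"]),
                                      self.REGISTRY)[0]

    def test_unregistered_predicate_raises(self):
        (rule,) = parse_rules("RULE r strength=0.5 duration=1: "
                              "IF ghost() THEN noop()")
        from wmdec.knowledge import UnknownPredicateError
        with pytest.raises(UnknownPredicateError):
            evaluate_condition(rule, {}, self.REGISTRY)

    @given(items=st.lists(st.sampled_from(["AA", "BB", "CC", "DD", "EE",
                                          "FF", "GG", "HH", "II", "JJ"]),
                          max_size=6, unique=True),
           neg=st.booleans())
    @settings(max_examples=60, deadline=None)
    def test_agrees_with_brute_force_enumeration(self, items, neg):
        text = ("RULE r strength=0.5 duration=1: "
                "IF X = present(AA) AND {}present(BB) AND Y = present(CC) "
                "THEN noop(X)").format("!" if neg else "")
        (rule,) = parse_rules(text)
        state = self._registry_state(items)
        ok, _ = evaluate_condition(rule, state, self.REGISTRY)
        expect = brute_force_match(rule, state, self.REGISTRY,
                                   ["AA", "BB", "CC", "DD", "EE", "FF",
                                    "GG", "HH", "II", "JJ"])
        assert ok == expect

    def test_compiled_condition_matches_interpreter(self, rng):
        (rule,) = parse_rules(
            "RULE r strength=0.5 duration=1: "
            "IF X = present(AA) AND !present(BB) AND count() >= 1 "
            "THEN noop(X)")
        for items in ([], ["AA"], ["BB"], ["AA", "BB"], ["AA", "CC"]):
            state = self._registry_state(items)
            ok, bindings = evaluate_condition(rule, state, self.REGISTRY)
            compiled = compile_condition(rule, self.REGISTRY)(state)
            assert (compiled is not None) == ok
            if ok:
                assert compiled == bindings


class TestSelectRule:
    def _rule(self, name, s):
        return parse_rules(f"RULE {name} strength={s} duration=1: "
                           "IF newcnt(ISM) >= 0 THEN noop()")[0]

    def test_empty_matches_gives_none(self, rng):
        assert select_rule([], set(), rng) is None

    def test_single_match_returned(self, rng):
        r = self._rule("only", 0.4)
        assert select_rule([(r, {})], set(), rng)[0] is r

    def test_highest_strength_wins(self, rng):
        lo, hi = self._rule("lo", 0.1), self._rule("hi", 0.9)
        assert select_rule([(lo, {}), (hi, {})], set(), rng)[0] is hi

    def test_active_rules_excluded(self, rng):
        r = self._rule("r", 0.9)
        assert select_rule([(r, {})], {r}, rng) is None

    def test_ties_broken_at_random_but_reproducibly(self):
        a, b = self._rule("a", 0.5), self._rule("b", 0.5)
        picks = {select_rule([(a, {}), (b, {})],
                             set(), random.Random(s))[0].name
                 for s in range(20)}
        assert picks == {"a", "b"}


class TestStrengthLearning:
    def test_positive_update_matches_closed_form(self):
        r = ProductionRule("r", [], None, strength=0.5, duration=1)
        s = update_rule_strength(r, "positive", LearningConfig())
        assert s == pytest.approx(0.5 + 0.5 * 0.00008)
        assert s == pytest.approx(0.50004)

    @pytest.mark.parametrize("s0,outcome", [(0.0, "negative"),
                                            (1.0, "positive")])
    def test_fixed_points(self, s0, outcome):
        r = ProductionRule("r", [], None, strength=s0, duration=1)
        assert update_rule_strength(r, outcome, LearningConfig()) == s0

    def test_iterated_positive_updates_converge_monotonically_to_one(self):
        r = ProductionRule("r", [], None, strength=0.3, duration=1)
        cfg = LearningConfig(eta=0.001)
        prev = r.strength
        for _ in range(100_000):
            s = update_rule_strength(r, "positive", cfg)
            assert prev <= s <= 1.0
            prev = s
        assert prev == pytest.approx(1.0, abs=1e-6)


class TestAssociationRules:
    def test_created_rule_has_standard_strength_and_duration(self):
        rule = create_association_rule("D9", "RIGHT", LearningConfig(), [])
        assert rule is not None
        assert rule.strength == 0.05
        assert rule.duration == 5
        assert rule.action.function == "do"
        assert rule.action.args == ("RIGHT",)

    def test_existing_rule_suppresses_creation(self):
        first = create_association_rule("D9", "RIGHT", LearningConfig(), [])
        assert create_association_rule("D9", "RIGHT", LearningConfig(),
                                       [first]) is None

    def test_condition_checks_task_set_stimulus_and_motor(self):
        rule = create_association_rule("D9", "RIGHT", LearningConfig(), [])
        fns = [t.function for t in rule.condition]
        assert fns == ["domts", "ltmsup", "ebacc", "gamsget"]
        assert association_rule_name("D9", "RIGHT") == "assoc-D9-RIGHT"
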