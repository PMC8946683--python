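"""Rule expressions, model validation, perturbations, phenotypes."""

import pytest

from g1snet.logic import (And, BooleanModel, Const, ModelValidationError,
                          NodeSpec, Not, Or, Perturbation, SignedEdge, Var,
                          parse_expression)


# --- expression parsing and evaluation -------------------------------------

@pytest.mark.parametrize("text, env, value", [
    ("A & !B", {"A": 1, "B": 0}, 1),
    ("A & !B", {"A": 1, "B": 1}, 0),
    ("A | B & C", {"A": 0, "B": 1, "C": 0}, 0),   # & binds tighter than |
    ("(A | B) & C", {"A": 1, "B": 0, "C": 1}, 1),
    ("!(A & B)", {"A": 1, "B": 0}, 1),
    ("!A & !B | C", {"A": 0, "B": 0, "C": 0}, 1),
    ("1", {}, 1),
    ("0 | A", {"A": 0}, 0),
])
def test_expression_evaluation(text, env, value):
    assert parse_expression(text).evaluate(env) == value


def test_expression_precedence_structure():
    expr = parse_expression("A | B & !C")
    assert isinstance(expr, Or)
    assert expr.operands[0] == Var("A")
    assert expr.operands[1] == And(Var("B"), Not(Var("C")))


def test_bnet_rendering_round_trips():
    for text in ("A & !B", "(A | B) & !(C & D)", "!A", "A & B | C"):
        expr = parse_expression(text)
        assert parse_expression(expr.to_bnet()) == expr


@pytest.mark.parametrize("bad", ["A &", "& B", "A (B)", "A ! B", "(A", "A)"])
def test_malformed_expressions_raise(bad):
    with pytest.raises(ModelValidationError):
        parse_expression(bad)


def test_three_valued_evaluation_prunes_unknowns():
    expr = parse_expression("A & !B | C")
    assert expr.evaluate3({"C": 1}) == 1          # C=1 decides the OR
    assert expr.evaluate3({"A": 0, "C": 0}) == 0  # both branches dead
    assert expr.evaluate3({"A": 1, "C": 0}) is None  # B unknown


# --- model validation -------------------------------------------------------

def _two_node(rules, edges):
    nodes = [NodeSpec("A"), NodeSpec("B")]
    return BooleanModel(nodes, edges, rules)


def test_rule_edge_consistency_enforced():
    # rule references a regulator with no declared edge
    with pytest.raises(ModelValidationError, match="mismatch"):
        _two_node({"A": "B", "B": "A & B"}, {SignedEdge("B", "A", 1),
                                             SignedEdge("A", "B", 1)})


def test_monotonicity_checked_against_edge_signs():
    # B's rule increases in A but the edge declares inhibition
    with pytest.raises(ModelValidationError, match="not monotone"):
        _two_node({"A": "B", "B": "A"},
                  {SignedEdge("B", "A", 1), SignedEdge("A", "B", -1)})


def test_non_monotone_rule_rejected():
    # XOR is non-monotone in both regulators
    nodes = [NodeSpec("A"), NodeSpec("B"), NodeSpec("C")]
    edges = {SignedEdge("A", "C", 1), SignedEdge("B", "C", 1),
             SignedEdge("C", "A", 1), SignedEdge("C", "B", 1)}
    with pytest.raises(ModelValidationError, match="not monotone"):
        BooleanModel(nodes, edges,
                     {"A": "C", "B": "C", "C": "(A & !B) | (!A & B)"})


def test_duplicate_names_rejected():
    with pytest.raises(ModelValidationError, match="duplicate"):
        BooleanModel([NodeSpec("A"), NodeSpec("A")], set(), {"A": "A"})


def test_output_nodes_must_be_sinks():
    nodes = [NodeSpec("A", "output"), NodeSpec("B")]
    edges = {SignedEdge("A", "B", 1), SignedEdge("B", "A", 1)}
    with pytest.raises(ModelValidationError, match="outgoing"):
        BooleanModel(nodes, edges, {"A": "B", "B": "A"})


def test_input_nodes_carry_no_rule():
    nodes = [NodeSpec("I", "input"), NodeSpec("A")]
    with pytest.raises(ModelValidationError, match="input"):
        BooleanModel(nodes, {SignedEdge("I", "A", 1)},
                     {"I": "A", "A": "I"})


# --- rule evaluation on states ---------------------------------------------

def test_evaluate_rule_on_states(toggle):
    assert toggle.evaluate_rule("A", (0, 0)) == 1
    assert toggle.evaluate_rule("A", (0, 1)) == 0
    with pytest.raises(KeyError):
        toggle.evaluate_rule("Z", (0, 0))
    with pytest.raises(ModelValidationError):
        toggle.evaluate_rule("A", (0, 0, 1))  # wrong dimension


# --- perturbations ----------------------------------------------------------

def test_perturbation_replaces_rules_with_constants(toggle):
    p = Perturbation.from_dict({"A": 1})
    m = toggle.apply_perturbation(p)
    assert m.rules["A"] == Const(1)
    assert m.rules["B"] == toggle.rules["B"]
    assert toggle.rules["A"] == Not(Var("B"))  # original untouched


def test_perturbation_is_idempotent(toggle):
    p = Perturbation.from_dict({"B": 0})
    once = toggle.apply_perturbation(p)
    twice = once.apply_perturbation(p)
    assert once.rules == twice.rules


def test_empty_perturbation_is_identity(toggle):
    assert toggle.apply_perturbation(Perturbation.from_dict({})) is toggle


def test_clamping_unknown_node_raises(toggle):
    with pytest.raises(KeyError):
        toggle.apply_perturbation(Perturbation.from_dict({"Z": 1}))


def test_clamp_values_restricted_to_bits():
    with pytest.raises(ModelValidationError):
        Perturbation.from_dict({"A": 2})


# --- phenotype classification ----------------------------------------------

def _outputs_model():
    nodes = [NodeSpec("x"), NodeSpec("Sen", "output"), NodeSpec("Apo", "output")]
    edges = {SignedEdge("x", "Sen", 1), SignedEdge("x", "Apo", 1),
             SignedEdge("x", "x", 1)}
    return BooleanModel(nodes, edges, {"x": "x", "Sen": "x", "Apo": "x"})


def test_classify_single_output_on():
    m = _outputs_model()
    assert m.classify_attractor([(0, 1, 0)]).label == "Sen"
    assert m.classify_attractor([(0, 0, 0)]).label == "None"


def test_classify_two_outputs_on_is_flagged_mixed():
    m = _outputs_model()
    ph = m.classify_attractor([(1, 1, 1)])
    assert ph.label == "Mixed" and ph.flagged


def test_classify_cycle_with_disagreeing_outputs_is_mixed():
    m = _outputs_model()
    ph = m.classify_attractor([(0, 1, 0), (0, 0, 0)])
    assert ph.label == "Mixed" and not ph.flagged


def test_classify_empty_attractor_rejected():
    with pytest.raises(ValueError):
        _outputs_model().classify_attractor([])
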