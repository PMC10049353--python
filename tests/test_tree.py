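"""Rollback engine: identities, the path-enumeration oracle, validation,
and serialisation round-trips."""

import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

from tbsepsis_cea.tree import (
    ChanceNode,
    DecisionNode,
    Payoff,
    TerminalNode,
    TreeStructureError,
    TreeValidationError,
    dump_tree,
    evaluate_alternatives,
    expected_payoff_by_enumeration,
    load_tree,
    rollback,
    tree_from_dict,
    tree_to_dict,
    validate,
)


def term(cost, eff, label="leaf"):
    return TerminalNode(label, Payoff(cost, eff))


def brute_force(node):
    """Independent recursive expectation, written without the package's
    enumerator: the oracle for rollback."""
    if isinstance(node, TerminalNode):
        return node.payoff.cost, node.payoff.effectiveness
    total_c = total_e = 0.0
    for p, child in node.branches:
        c, e = brute_force(child)
        total_c += p * c
        total_e += p * e
    return total_c, total_e


# ---------------------------------------------------------------- rollback

def test_terminal_rollback_is_identity():
    assert rollback(term(195, 0.6)) == Payoff(195, 0.6)


def test_symmetric_chance_node_averages():
    node = ChanceNode("c", ((0.5, term(0, 1)), (0.5, term(100, 0))))
    assert rollback(node) == Payoff(50, 0.5)


def test_three_level_tree_matches_brute_force_oracle():
    tree = ChanceNode(
        "root",
        (
            (0.5, ChanceNode("a", ((0.42, term(10, 0.2)), (0.58, term(20, 0.9))))),
            (0.5, ChanceNode("b", ((0.2, term(5, 0.0)),
                                   (0.8, ChanceNode("b2", ((0.3, term(7, 0.1)),
                                                           (0.7, term(2, 1.0)))))))),
        ),
    )
    rb = rollback(tree)
    c, e = brute_force(tree)
    assert rb.cost == pytest.approx(c, rel=1e-12)
    assert rb.effectiveness == pytest.approx(e, rel=1e-12)
    en = expected_payoff_by_enumeration(tree)
    assert en.cost == pytest.approx(c, rel=1e-12)
    assert en.effectiveness == pytest.approx(e, rel=1e-12)


@st.composite
def chance_trees(draw, depth=0):
    if depth >= 3 or draw(st.booleans()) and depth > 0:
        cost = draw(st.floats(0, 1000, allow_nan=False))
        eff = draw(st.floats(0, 10, allow_nan=False))
        return term(cost, eff, label=f"leaf{depth}")
    k = draw(st.integers(2, 3))
    weights = [draw(st.floats(0.05, 1.0)) for _ in range(k)]
    total = sum(weights)
    children = [draw(chance_trees(depth=depth + 1)) for _ in range(k)]
    return ChanceNode(f"n{depth}", tuple((w / total, c) for w, c in zip(weights, children)))


@given(chance_trees())
def test_rollback_equals_enumeration_on_random_trees(tree):
    rb = rollback(tree)
    en = expected_payoff_by_enumeration(tree)
    assert math.isclose(rb.cost, en.cost, rel_tol=1e-12, abs_tol=1e-12)
    assert math.isclose(rb.effectiveness, en.effectiveness, rel_tol=1e-12, abs_tol=1e-12)


@given(chance_trees(), st.floats(0.1, 10), st.floats(0, 5))
def test_rollback_is_linear_in_payoffs(tree, k, c):
    """Scaling all leaf costs by k scales expected cost by k; adding c to
    all leaf effectiveness adds c."""

    def transform(node):
        if isinstance(node, TerminalNode):
            return TerminalNode(node.label, Payoff(node.payoff.cost * k,
                                                   node.payoff.effectiveness + c))
        return ChanceNode(node.label, tuple((p, transform(ch)) for p, ch in node.branches))

    before = rollback(tree)
    after = rollback(transform(tree))
    assert math.isclose(after.cost, before.cost * k, rel_tol=1e-9, abs_tol=1e-9)
    assert math.isclose(after.effectiveness, before.effectiveness + c,
                        rel_tol=1e-9, abs_tol=1e-9)


@given(chance_trees())
def test_branch_reordering_leaves_rollback_unchanged(tree):
    def reverse(node):
        if isinstance(node, TerminalNode):
            return node
        return ChanceNode(node.label, tuple((p, reverse(ch))
                                            for p, ch in reversed(node.branches)))

    a, b = rollback(tree), rollback(reverse(tree))
    assert math.isclose(a.cost, b.cost, rel_tol=1e-12, abs_tol=1e-12)
    assert math.isclose(a.effectiveness, b.effectiveness, rel_tol=1e-12, abs_tol=1e-12)


# ------------------------------------------------------------- validation

def test_wellformed_tree_has_no_violations():
    node = ChanceNode("ok", ((0.3, term(1, 1)), (0.7, term(2, 0))))
    assert validate(node) == []


def test_probability_sum_violation_names_the_node():
    node = ChanceNode("bad_sum", ((0.6, term(1, 1)), (0.6, term(2, 0))))
    violations = validate(node)
    assert len(violations) == 1
    assert violations[0].kind == "probability_sum"
    assert violations[0].node_label == "bad_sum"
    with pytest.raises(TreeValidationError):
        rollback(node)


def test_negative_probability_is_a_range_violation():
    node = ChanceNode("neg", ((-0.1, term(1, 1)), (1.1, term(2, 0))))
    kinds = [v.kind for v in validate(node)]
    assert kinds.count("probability_range") == 2


def test_payoff_rejects_negative_and_nonfinite():
    with pytest.raises(ValueError):
        Payoff(-1, 0)
    with pytest.raises(ValueError):
        Payoff(0, -0.5)
    with pytest.raises(ValueError):
        Payoff(float("nan"), 0)


# ------------------------------------------------------------- decisions

def test_evaluate_alternatives_returns_one_payoff_per_arm():
    root = DecisionNode("root", (("A", term(10, 1)), ("B", term(20, 2))))
    assert evaluate_alternatives(root) == {"A": Payoff(10, 1), "B": Payoff(20, 2)}


def test_identical_subtrees_give_equal_payoffs():
    sub = ChanceNode("c", ((0.25, term(4, 0.5)), (0.75, term(8, 0.1))))
    root = DecisionNode("root", (("A", sub), ("B", sub)))
    out = evaluate_alternatives(root)
    assert out["A"] == out["B"]


def test_decision_node_requires_two_alternatives():
    with pytest.raises(TreeStructureError):
        DecisionNode("solo", (("only", term(1, 1)),))


def test_rollback_refuses_decision_roots():
    root = DecisionNode("root", (("A", term(1, 1)), ("B", term(2, 2))))
    with pytest.raises(TreeStructureError):
        rollback(root)


# ---------------------------------------------------------- serialisation

def test_round_trip_is_lossless(tmp_path):
    tree = DecisionNode(
        "root",
        (
            ("treat_all", ChanceNode("c", ((0.135, term(212.42, 0.0, "dead")),
                                           (0.865, term(212.42, 0.9, "alive"))))),
            ("selective", term(17.42, 0.95, "alive")),
        ),
    )
    for name in ("tree.json", "tree.yaml"):
        path = tmp_path / name
        dump_tree(tree, path)
        assert load_tree(path) == tree


def test_probability_expressions_resolve_against_parameters():
    obj = {
        "kind": "chance",
        "label": "tb_status",
        "branches": [
            {"probability": "prevalence_tb",
             "child": {"kind": "terminal", "label": "tb",
                       "payoff": {"cost": 1, "effectiveness": 0}}},
            {"probability": "1 - prevalence_tb",
             "child": {"kind": "terminal", "label": "no_tb",
                       "payoff": {"cost": 0, "effectiveness": 1}}},
        ],
    }
    tree = tree_from_dict(obj, parameters={"prevalence_tb": 0.5})
    assert rollback(tree) == Payoff(0.5, 0.5)
    assert tree_to_dict(tree)["branches"][0]["probability"] == 0.5
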