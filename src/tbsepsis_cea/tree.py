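"""Decision-tree data model and expected-value rollback.

The tree carries a two-dimensional payoff — cost in USD and effectiveness in
quality-adjusted life years (QALYs) — at every terminal node.  Costs follow a
cost-at-leaf convention: each leaf stores the *total* cost accrued along its
root-to-leaf path, so rollback is a plain probability-weighted average and
agrees exactly with exhaustive path enumeration.

Three node kinds exist:

* :class:`TerminalNode` — a health state with its payoff;
* :class:`ChanceNode` — ordered probabilistic branches that must sum to one;
* :class:`DecisionNode` — the root choice between strategies.  It is never
  averaged over: each alternative is rolled back separately and the
  cost-effectiveness layer compares them.

Nodes are immutable; sensitivity analysis rebuilds trees from modified
parameter sets instead of mutating nodes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Union

import yaml

__all__ = [
    "Payoff",
    "TerminalNode",
    "ChanceNode",
    "DecisionNode",
    "Node",
    "Violation",
    "TreeValidationError",
    "TreeStructureError",
    "validate",
    "rollback",
    "evaluate_alternatives",
    "enumerate_paths",
    "expected_payoff_by_enumeration",
    "tree_to_dict",
    "tree_from_dict",
    "dump_tree",
    "load_tree",
]

#: Chance-node probabilities must sum to 1 within this tolerance.  Inputs are
#: stored as given and never silently renormalised — a bad sum is reported so
#: that transcription errors in parameter tables surface instead of vanishing.
PROBABILITY_SUM_TOL = 1e-9


class TreeValidationError(ValueError):
    """A tree failed probability validation (sum or range)."""

    def __init__(self, violations: list["Violation"]):
        self.violations = violations
        super().__init__("; ".join(str(v) for v in violations))


class TreeStructureError(ValueError):
    """The node graph is not a tree (cycle / node revisited on a path)."""


@dataclass(frozen=True)
class Payoff:
    """Cost (USD) and effectiveness (QALY) pair attached to a leaf or arm."""

    cost: float
    effectiveness: float

    def __post_init__(self) -> None:
        for name in ("cost", "effectiveness"):
            v = getattr(self, name)
            if not (v == v and abs(v) != float("inf")):
                raise ValueError(f"Payoff.{name} must be finite, got {v!r}")
        if self.cost < 0:
            raise ValueError(f"Payoff.cost must be >= 0, got {self.cost}")
        if self.effectiveness < 0:
            raise ValueError(
                f"Payoff.effectiveness must be >= 0, got {self.effectiveness}"
            )


@dataclass(frozen=True)
class TerminalNode:
    label: str
    payoff: Payoff


@dataclass(frozen=True)
class ChanceNode:
    label: str
    branches: tuple[tuple[float, "Node"], ...]

    def __post_init__(self) -> None:
        if len(self.branches) < 2:
            raise ValueError(
                f"ChanceNode {self.label!r} needs >= 2 branches, got {len(self.branches)}"
            )
        object.__setattr__(self, "branches", tuple((float(p), c) for p, c in self.branches))


@dataclass(frozen=True)
class DecisionNode:
    label: str
    alternatives: tuple[tuple[str, "Node"], ...]

    def __post_init__(self) -> None:
        if len(self.alternatives) < 2:
            raise TreeStructureError(
                f"DecisionNode {self.label!r} needs >= 2 alternatives, "
                f"got {len(self.alternatives)}"
            )


Node = Union[TerminalNode, ChanceNode, DecisionNode]


@dataclass(frozen=True)
class Violation:
    """One validation failure, naming the offending node."""

    node_label: str
    kind: str  # "probability_sum" | "probability_range" | "cycle"
    detail: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"[{self.kind}] {self.node_label}: {self.detail}"


def _children(node: Node) -> Iterator[Node]:
    if isinstance(node, ChanceNode):
        for _, child in node.branches:
            yield child
    elif isinstance(node, DecisionNode):
        for _, child in node.alternatives:
            yield child


def validate(node: Node) -> list[Violation]:
    """Collect violations: probability ranges, branch sums, and cycles.

    Returns an empty list iff every chance node has probabilities in [0, 1]
    summing to 1 within :data:`PROBABILITY_SUM_TOL` and no node repeats on any
    root-to-leaf path.  Violations are returned, never raised.
    """
    violations: list[Violation] = []

    def visit(n: Node, on_path: set[int]) -> None:
        if id(n) in on_path:
            violations.append(
                Violation(getattr(n, "label", "?"), "cycle", "node revisited on its own path")
            )
            return
        if isinstance(n, ChanceNode):
            total = 0.0
            for p, _ in n.branches:
                total += p
                if not (0.0 <= p <= 1.0):
                    violations.append(
                        Violation(n.label, "probability_range", f"branch probability {p} outside [0, 1]")
                    )
            if abs(total - 1.0) > PROBABILITY_SUM_TOL:
                violations.append(
                    Violation(n.label, "probability_sum", f"branch probabilities sum to {total!r}, not 1")
                )
        on_path = on_path | {id(n)}
        for child in _children(n):
            visit(child, on_path)

    visit(node, set())
    return violations


def rollback(node: Node) -> Payoff:
    """Expected (cost, effectiveness) of a terminal or chance subtree.

    A terminal node returns its payoff; a chance node returns the
    probability-weighted sum of its children's rollbacks, componentwise.
    Decision nodes are handled by :func:`evaluate_alternatives`, not here.

    Raises :class:`TreeValidationError` if the subtree fails :func:`validate`.
    """
    if isinstance(node, DecisionNode):
        raise TreeStructureError(
            "rollback() takes a terminal or chance node; use evaluate_alternatives() "
            "for a decision root"
        )
    violations = validate(node)
    if violations:
        raise TreeValidationError(violations)
    return _rollback_unchecked(node)


def _rollback_unchecked(node: Node) -> Payoff:
    if isinstance(node, TerminalNode):
        return node.payoff
    assert isinstance(node, ChanceNode)
    cost = 0.0
    eff = 0.0
    for p, child in node.branches:
        sub = _rollback_unchecked(child)
        cost += p * sub.cost
        eff += p * sub.effectiveness
    return Payoff(cost, eff)


def evaluate_alternatives(root: DecisionNode) -> dict[str, Payoff]:
    """Roll back every alternative of a decision root.

    No alternative is *selected*: strategy comparison belongs to the
    cost-effectiveness layer, not to expected-value maximisation.
    """
    if not isinstance(root, DecisionNode):
        raise TreeStructureError("evaluate_alternatives() requires a DecisionNode root")
    return {name: rollback(child) for name, child in root.alternatives}


def enumerate_paths(node: Node) -> Iterator[tuple[tuple[str, ...], float, Payoff]]:
    """Yield (branch labels, path probability, leaf payoff) per root-to-leaf path.

    Decision alternatives are treated as label-only edges (probability 1), so
    enumeration of a decision root covers every arm.  This is the independent
    route against which rollback is checked.
    """

    def walk(n: Node, labels: tuple[str, ...], prob: float):
        if isinstance(n, TerminalNode):
            yield labels + (n.label,), prob, n.payoff
        elif isinstance(n, ChanceNode):
            for p, child in n.branches:
                yield from walk(child, labels + (n.label,), prob * p)
        else:
            for name, child in n.alternatives:
                yield from walk(child, labels + (name,), prob)

    yield from walk(node, (), 1.0)


def expected_payoff_by_enumeration(node: Node) -> Payoff:
    """Sum over paths of P(path) x leaf payoff — the brute-force oracle."""
    cost = 0.0
    eff = 0.0
    for _, p, payoff in enumerate_paths(node):
        cost += p * payoff.cost
        eff += p * payoff.effectiveness
    return Payoff(cost, eff)


# --------------------------------------------------------------------------
# Serialisation: a JSON/YAML dialect with node "kind" tags.  Branch
# probabilities may be numbers or strings naming entries of a parameter
# mapping supplied at load time ("expressions" of the form "name" or
# "1 - name"), so a stored model file can reference a parameter table.
# --------------------------------------------------------------------------

def _prob_to_obj(p: float) -> float:
    return float(p)


def _resolve_prob(value, parameters: Mapping[str, float] | None) -> float:
    if isinstance(value, (int, float)):
        return float(value)
    if isinstance(value, str):
        if parameters is None:
            raise KeyError(
                f"probability expression {value!r} needs a parameter mapping"
            )
        expr = value.strip()
        if expr.startswith("1 -") or expr.startswith("1-"):
            name = expr.split("-", 1)[1].strip()
            return 1.0 - float(parameters[name])
        return float(parameters[expr])
    raise TypeError(f"unsupported probability value {value!r}")


def tree_to_dict(node: Node) -> dict:
    if isinstance(node, TerminalNode):
        return {
            "kind": "terminal",
            "label": node.label,
            "payoff": {"cost": node.payoff.cost, "effectiveness": node.payoff.effectiveness},
        }
    if isinstance(node, ChanceNode):
        return {
            "kind": "chance",
            "label": node.label,
            "branches": [
                {"probability": _prob_to_obj(p), "child": tree_to_dict(c)}
                for p, c in node.branches
            ],
        }
    return {
        "kind": "decision",
        "label": node.label,
        "alternatives": [
            {"name": name, "child": tree_to_dict(c)} for name, c in node.alternatives
        ],
    }


def tree_from_dict(obj: dict, parameters: Mapping[str, float] | None = None) -> Node:
    kind = obj.get("kind")
    if kind == "terminal":
        p = obj["payoff"]
        return TerminalNode(obj["label"], Payoff(float(p["cost"]), float(p["effectiveness"])))
    if kind == "chance":
        return ChanceNode(
            obj["label"],
            tuple(
                (_resolve_prob(b["probability"], parameters), tree_from_dict(b["child"], parameters))
                for b in obj["branches"]
            ),
        )
    if kind == "decision":
        return DecisionNode(
            obj["label"],
            tuple((a["name"], tree_from_dict(a["child"], parameters)) for a in obj["alternatives"]),
        )
    raise ValueError(f"unknown node kind {kind!r}")


def dump_tree(node: Node, path, fmt: str | None = None) -> None:
    """Write a tree as JSON or YAML (inferred from the file suffix)."""
    path = str(path)
    obj = tree_to_dict(node)
    if fmt is None:
        fmt = "yaml" if path.endswith((".yaml", ".yml")) else "json"
    with open(path, "w") as fh:
        if fmt == "yaml":
            yaml.safe_dump(obj, fh, sort_keys=False)
        else:
            json.dump(obj, fh, indent=2, sort_keys=False)


def load_tree(path, parameters: Mapping[str, float] | None = None) -> Node:
    path = str(path)
    with open(path) as fh:
        if path.endswith((".yaml", ".yml")):
            obj = yaml.safe_load(fh)
        else:
            obj = json.load(fh)
    return tree_from_dict(obj, parameters)
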