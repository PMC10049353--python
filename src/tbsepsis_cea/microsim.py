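"""Patient-level Monte-Carlo simulation and parameter perturbation.

The microsimulator is the stochastic oracle for the analytic rollback:
each simulated patient walks the decision tree, drawing a branch at every
chance node, and accrues the leaf's cost and QALYs.  Cohort means are
unbiased estimators of the rollback expectations, so the two routes can be
cross-checked (|mean - rollback| within a few standard errors).

Sampling is vectorised per chance node, visited in preorder: all patients
standing at a node draw their branch from one named RNG stream in patient
order.  That makes cohorts reproducible byte-for-byte given (tree, n,
seed), independent of any execution plan.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .parameters import COST_FIELDS, PROBABILITY_FIELDS, ParameterSet
from .tree import ChanceNode, DecisionNode, Node, TerminalNode, TreeValidationError, validate

__all__ = [
    "SimulatedCohort",
    "CohortSummary",
    "simulate_cohort",
    "perturb_parameters",
    "write_cohort_csv",
    "write_summary_json",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CohortSummary:
    n: int
    mean_cost: float
    mean_qaly: float
    se_cost: float
    se_qaly: float
    state_frequencies: dict[str, int]


@dataclass(frozen=True)
class SimulatedCohort:
    """Per-patient outcomes of one simulated cohort."""

    n: int
    seed: int
    paths: tuple[str, ...]  # branch-label path per patient, "/"-joined
    terminal_states: tuple[str, ...]
    costs: np.ndarray
    qalys: np.ndarray

    def summary(self) -> CohortSummary:
        states, counts = np.unique(np.asarray(self.terminal_states), return_counts=True)
        ddof = 1 if self.n > 1 else 0
        return CohortSummary(
            n=self.n,
            mean_cost=float(self.costs.mean()),
            mean_qaly=float(self.qalys.mean()),
            se_cost=float(self.costs.std(ddof=ddof) / np.sqrt(self.n)),
            se_qaly=float(self.qalys.std(ddof=ddof) / np.sqrt(self.n)),
            state_frequencies={str(s): int(c) for s, c in zip(states, counts)},
        )


def simulate_cohort(tree: Node, n: int, seed: int) -> SimulatedCohort:
    """Walk ``n`` patients through a validated chance/terminal tree.

    Decision roots are refused: simulate each arm separately.  The seed is
    mandatory — there is no implicit entropy.
    """
    if isinstance(tree, DecisionNode):
        raise ValueError("simulate per arm: pass a chance/terminal subtree, not a decision root")
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    violations = validate(tree)
    if violations:
        raise TreeValidationError(violations)

    rng = np.random.default_rng(seed)
    # leaf index per patient, assigned by walking nodes in preorder
    leaf_of = np.full(n, -1, dtype=np.int64)
    leaves: list[TerminalNode] = []
    leaf_paths: list[str] = []

    def walk(node: Node, patients: np.ndarray, labels: tuple[str, ...]) -> None:
        if isinstance(node, TerminalNode):
            idx = len(leaves)
            leaves.append(node)
            leaf_paths.append("/".join(labels + (node.label,)))
            leaf_of[patients] = idx
            return
        assert isinstance(node, ChanceNode)
        probs = np.array([p for p, _ in node.branches])
        # one categorical draw per patient standing at this node, in
        # patient order; cumulative inverse-CDF keeps draws reproducible
        u = rng.random(patients.size)
        choice = np.searchsorted(np.cumsum(probs), u, side="right")
        choice = np.minimum(choice, len(probs) - 1)  # guard fp roundoff at u ~ 1
        for b, (_, child) in enumerate(node.branches):
            sub = patients[choice == b]
            if sub.size:
                walk(child, sub, labels + (node.label,))

    walk(tree, np.arange(n, dtype=np.int64), ())

    costs = np.array([leaf.payoff.cost for leaf in leaves])[leaf_of]
    qalys = np.array([leaf.payoff.effectiveness for leaf in leaves])[leaf_of]
    paths = tuple(np.array(leaf_paths, dtype=object)[leaf_of])
    states = tuple(np.array([leaf.label for leaf in leaves], dtype=object)[leaf_of])
    return SimulatedCohort(
        n=n, seed=seed, paths=paths, terminal_states=states, costs=costs, qalys=qalys
    )


def perturb_parameters(
    params: ParameterSet, mode: str, seed: int, include_diagnostics: bool = False
) -> ParameterSet:
    """Draw one perturbed parameter set, independently per parameter.

    ``uniform_in_range`` draws uniformly inside each published range and
    falls back to +/-10% (with a logged notice) for parameters without one;
    ``pct10`` draws uniformly in [0.9, 1.1] x base for everything.
    Probabilities and disability weights are clipped to [0, 1].  Parameters
    are visited in a fixed order (scalar fields, then — when
    ``include_diagnostics`` — diagnostic accuracies and costs sorted by
    key), so draws are deterministic per seed.  Zero-width ranges leave the
    base value untouched.
    """
    if mode not in ("uniform_in_range", "pct10"):
        raise ValueError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(seed)
    out = params

    def draw(name: str, base: float, rng_bounds, is_fraction: bool) -> float:
        if mode == "uniform_in_range" and rng_bounds is not None:
            lo, hi = rng_bounds
        else:
            if mode == "uniform_in_range":
                logger.info("parameter %s has no range; falling back to +/-10%%", name)
            lo, hi = base * 0.9, base * 1.1
        v = float(rng.uniform(lo, hi))
        return min(1.0, max(0.0, v)) if is_fraction else max(0.0, v)

    for name in PROBABILITY_FIELDS + COST_FIELDS:
        p = getattr(params, name)
        bounds = (p.low, p.high) if p.has_range else None
        if bounds is not None and bounds[0] == bounds[1]:
            continue  # zero-width range: keep the base value untouched
        value = draw(name, p.value, bounds, name in PROBABILITY_FIELDS)
        out = out.with_value(name, value)

    if include_diagnostics:
        for key in sorted(params.diagnostics):
            for attr in ("sensitivity", "specificity", "unit_cost"):
                dotted = f"diagnostics.{key}.{attr}"
                base = params.value_of(dotted)
                value = draw(dotted, base, None, attr != "unit_cost")
                out = out.with_value(dotted, value)
    return out


def write_cohort_csv(cohort: SimulatedCohort, path) -> None:
    df = pd.DataFrame(
        {
            "patient_id": np.arange(cohort.n),
            "path": cohort.paths,
            "terminal_state": cohort.terminal_states,
            "cost": cohort.costs,
            "qaly": cohort.qalys,
        }
    )
    df.to_csv(path, index=False, float_format="%.10g")


def write_summary_json(cohort: SimulatedCohort, path) -> None:
    s = cohort.summary()
    payload = {
        "n": s.n,
        "seed": cohort.seed,
        "mean_cost": s.mean_cost,
        "mean_qaly": s.mean_qaly,
        "se_cost": s.se_cost,
        "se_qaly": s.se_qaly,
        "state_frequencies": s.state_frequencies,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
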