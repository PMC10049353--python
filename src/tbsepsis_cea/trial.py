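"""Builders for the six model arms of the TB-sepsis case study.

Two treatment strategies — immediate empiric anti-TB therapy for every
enrollee ("treat all") versus diagnosis-dependent standard of care
("selective treatment") — are instantiated for each of three diagnostic
strategies (urine LAM, sputum Xpert MTB/RIF, combined LAM+Xpert).

Terminal payoffs follow the cost-at-leaf convention: each leaf carries the
full cost accrued on its path (diagnostics + any anti-TB treatment) and the
QALYs of its terminal health state over the model horizon.  Standard-of-care
antibiotics and hospitalisation are costed at zero in both arms; they cancel
in the increment.
"""

from __future__ import annotations

from enum import Enum

from .diagnostics import (
    DiagnosticProfile,
    npv,
    ppv,
    prob_test_positive,
)
from .parameters import ParameterSet, StructureConfig
from .tree import ChanceNode, DecisionNode, Node, Payoff, TerminalNode, rollback

__all__ = [
    "HealthState",
    "qaly_for_state",
    "treated_outcome",
    "build_treat_all",
    "build_selective",
    "build_decision_root",
    "expected_outcomes",
    "ARM_NAMES",
]

ARM_NAMES = ("treat_all", "selective")


class HealthState(str, Enum):
    """Terminal health states; death maps to zero QALYs unconditionally."""

    dead = "dead"
    survived_tb_treated = "survived_tb_treated"
    survived_tb_untreated = "survived_tb_untreated"
    survived_no_tb = "survived_no_tb"


_STATE_WEIGHT_FIELD = {
    HealthState.survived_tb_treated: "dw_tb_treatment",
    HealthState.survived_tb_untreated: "dw_tb_hiv",
    HealthState.survived_no_tb: "dw_hiv_art",
}


def qaly_for_state(
    state: HealthState, params: ParameterSet, structure: StructureConfig
) -> float:
    """QALYs accrued in a terminal state over the model horizon.

    Survivors accrue (1 - disability weight) x horizon.  When the acute
    sepsis decrement is enabled, the severe-sepsis disability weight is
    additionally applied over the acute phase (``structure.acute_days``,
    capped at the horizon), i.e. the survivor loses
    (1 - dw_state) * dw_sepsis * acute_years of the healthy-equivalent time.
    """
    if state is HealthState.dead:
        return 0.0
    h = params.horizon_years
    dw = getattr(params, _STATE_WEIGHT_FIELD[state]).value
    if structure.sepsis_dw_applied:
        acute = min(structure.acute_days / 365.0, h)
        return (1.0 - dw) * (h - params.dw_severe_sepsis.value * acute)
    return (1.0 - dw) * h


def _leaf(state: HealthState, cost: float, params, structure, label: str | None = None) -> TerminalNode:
    return TerminalNode(
        label or state.value,
        Payoff(cost=cost, effectiveness=qaly_for_state(state, params, structure)),
    )


def _binary(label: str, p_first: float, first: Node, second: Node) -> ChanceNode:
    return ChanceNode(label, ((p_first, first), (1.0 - p_first, second)))


def treated_outcome(
    params: ParameterSet,
    structure: StructureConfig,
    path_cost: float,
    *,
    empiric: bool,
    survivor_state: HealthState = HealthState.survived_tb_treated,
    label: str = "treated_tb",
) -> Node:
    """Outcome subtree for a TB patient on anti-TB therapy.

    ``mortality_direct`` applies the directly measured on-treatment mortality.
    ``success_mediated`` splits by rifampin resistance: susceptible patients
    succeed (survive) with the sensitive-TB success rate, else die; resistant
    patients follow ``structure.resistance_outcome`` and, if they survive,
    remain in the TB/HIV state.  ``empiric_success_mediated`` applies the
    success/resistance factorisation only to empiric therapy (``empiric=True``:
    the treat-all arm and delayed empiric treatment) and the direct mortality
    to standard-of-care confirmed-TB treatment.
    """
    mode = structure.mortality_mode
    if mode == "empiric_success_mediated":
        mode = "success_mediated" if empiric else "mortality_direct"

    if mode == "mortality_direct":
        return _binary(
            label,
            params.p_death_treated_tb.value,
            _leaf(HealthState.dead, path_cost, params, structure),
            _leaf(survivor_state, path_cost, params, structure),
        )

    # success-mediated
    p_death_resistant = (
        params.p_death_untreated_tb.value
        if structure.resistance_outcome == "untreated_mortality"
        else params.p_death_treated_tb.value
    )
    susceptible = _binary(
        f"{label}/susceptible",
        params.p_treatment_success_sensitive.value,
        _leaf(survivor_state, path_cost, params, structure, label="treatment_success"),
        _leaf(HealthState.dead, path_cost, params, structure, label="treatment_failure_death"),
    )
    resistant = _binary(
        f"{label}/resistant",
        p_death_resistant,
        _leaf(HealthState.dead, path_cost, params, structure),
        _leaf(HealthState.survived_tb_untreated, path_cost, params, structure),
    )
    return _binary(label, params.p_resistance.value, resistant, susceptible)


def _suspect_no_tb(params, structure, path_cost: float, label: str) -> Node:
    """Outcome for a patient without TB (sepsis of another cause)."""
    return _binary(
        label,
        params.p_death_suspect_no_tb.value,
        _leaf(HealthState.dead, path_cost, params, structure),
        _leaf(HealthState.survived_no_tb, path_cost, params, structure),
    )


def _untreated_tb(params, structure, path_cost: float, label: str = "untreated_tb") -> Node:
    return _binary(
        label,
        params.p_death_untreated_tb.value,
        _leaf(HealthState.dead, path_cost, params, structure),
        _leaf(HealthState.survived_tb_untreated, path_cost, params, structure),
    )


def _missed_tb(params: ParameterSet, structure: StructureConfig, base_cost: float) -> Node:
    """Subtree for a TB patient whose test was negative (standard of care).

    Without delayed empiric therapy the patient follows untreated-TB
    mortality.  With it, the patient first faces the initial untreated
    period (day-7 mortality of non-confirmed TB suspects); survivors receive
    delayed empiric therapy with the uptake probability, otherwise they
    remain untreated.
    """
    if not structure.soc_delayed_empiric:
        return _untreated_tb(params, structure, base_cost, label="missed_tb")

    uptake = (
        params.p_delayed_empiric.value
        if structure.delayed_uptake is None
        else structure.delayed_uptake
    )
    delayed_cost = base_cost + (
        params.cost_tb_treatment.value if structure.count_delayed_treatment_cost else 0.0
    )
    delayed = treated_outcome(
        params,
        structure,
        delayed_cost,
        empiric=True,
        survivor_state=HealthState[structure.delayed_survivor_state],
        label="delayed_treatment",
    )
    if uptake >= 1.0:
        survived_initial: Node = delayed
    elif uptake <= 0.0:
        survived_initial = _untreated_tb(params, structure, base_cost)
    else:
        survived_initial = _binary(
            "delayed_uptake",
            uptake,
            delayed,
            _untreated_tb(params, structure, base_cost),
        )
    return _binary(
        "missed_tb",
        params.p_death_suspect_no_tb.value,
        _leaf(HealthState.dead, base_cost, params, structure, label="death_initial_period"),
        survived_initial,
    )


def _diagnostic(params: ParameterSet, diagnostic: str) -> DiagnosticProfile:
    try:
        return params.diagnostics[diagnostic]
    except KeyError:
        raise KeyError(
            f"unknown diagnostic {diagnostic!r}; available: {sorted(params.diagnostics)}"
        ) from None


def build_treat_all(
    params: ParameterSet, diagnostic: str, structure: StructureConfig
) -> Node:
    """Immediate empiric therapy arm: every patient is tested and treated."""
    test = _diagnostic(params, diagnostic)
    base = (test.unit_cost if structure.arm_shared_diagnostic_cost else 0.0) + (
        params.cost_tb_treatment.value
    )
    prev = params.prevalence_tb.value
    return _binary(
        "tb_status",
        prev,
        treated_outcome(params, structure, base, empiric=True),
        _suspect_no_tb(params, structure, base, label="no_tb"),
    )


def build_selective(
    params: ParameterSet, diagnostic: str, structure: StructureConfig
) -> Node:
    """Standard-of-care arm: treat on a positive test (plus, optionally,
    delayed empiric therapy for missed TB).

    Supports both factorisations: test-result-first (marginal positivity,
    then PPV/NPV) and disease-first (prevalence, then conditional test
    result).  They roll back to identical expectations.
    """
    test = _diagnostic(params, diagnostic)
    prev = params.prevalence_tb.value
    diag_cost = test.unit_cost if structure.arm_shared_diagnostic_cost else 0.0
    treat_cost = diag_cost + params.cost_tb_treatment.value

    confirmed = treated_outcome(params, structure, treat_cost, empiric=False, label="confirmed_tb")
    false_pos = _suspect_no_tb(params, structure, treat_cost, label="treated_no_tb")
    missed = _missed_tb(params, structure, diag_cost)
    true_neg = _suspect_no_tb(params, structure, diag_cost, label="no_tb")

    if structure.factorization == "test_first":
        p_pos = prob_test_positive(prev, test)
        positive = _binary("tb_given_positive", ppv(prev, test), confirmed, false_pos)
        negative = _binary("tb_given_negative", 1.0 - npv(prev, test), missed, true_neg)
        return _binary("test_result", p_pos, positive, negative)

    tb = _binary("test_given_tb", test.sensitivity, confirmed, missed)
    no_tb = _binary("test_given_no_tb", test.specificity, true_neg, false_pos)
    return _binary("tb_status", prev, tb, no_tb)


def build_decision_root(
    params: ParameterSet, diagnostic: str, structure: StructureConfig
) -> DecisionNode:
    """Decision root comparing the two arms for one diagnostic strategy."""
    return DecisionNode(
        f"strategy[{diagnostic}]",
        (
            ("treat_all", build_treat_all(params, diagnostic, structure)),
            ("selective", build_selective(params, diagnostic, structure)),
        ),
    )


def expected_outcomes(
    params: ParameterSet, diagnostic: str, arm: str, structure: StructureConfig
) -> Payoff:
    """Expected (cost, QALY) of one arm under one diagnostic strategy."""
    if arm == "treat_all":
        return rollback(build_treat_all(params, diagnostic, structure))
    if arm == "selective":
        return rollback(build_selective(params, diagnostic, structure))
    raise ValueError(f"unknown arm {arm!r}; expected one of {ARM_NAMES}")
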