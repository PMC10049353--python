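"""Arm builders: health-state QALYs, treated-outcome factorisations, cost
accounting, and rollback/enumeration agreement for all six arms."""

import math

import pytest

from tbsepsis_cea import (
    HealthState,
    StructureConfig,
    build_selective,
    build_treat_all,
    expected_outcomes,
    expected_payoff_by_enumeration,
    qaly_for_state,
    rollback,
    treated_outcome,
    validate,
)
from tbsepsis_cea.tree import enumerate_paths

DIAGNOSTICS = ("lam", "xpert", "combined")
ARMS = ("treat_all", "selective")


# ----------------------------------------------------------------- QALYs

def test_death_accrues_zero_qalys(base_params, plain_structure):
    assert qaly_for_state(HealthState.dead, base_params, plain_structure) == 0.0


def test_survivor_qalys_are_one_minus_disability_weight_times_horizon(
    base_params, plain_structure
):
    assert qaly_for_state(HealthState.survived_no_tb, base_params,
                          plain_structure) == pytest.approx(0.947, abs=1e-12)
    assert qaly_for_state(HealthState.survived_tb_treated, base_params,
                          plain_structure) == pytest.approx(0.9, abs=1e-12)
    assert qaly_for_state(HealthState.survived_tb_untreated, base_params,
                          plain_structure) == pytest.approx(0.601, abs=1e-12)


def test_acute_sepsis_decrement_reduces_survivor_qalys(base_params):
    with_sepsis = StructureConfig(sepsis_dw_applied=True)
    q = qaly_for_state(HealthState.survived_no_tb, base_params, with_sepsis)
    # (1 - 0.053) * (1 - 0.31 * 7/365) over a 1-year horizon
    assert q == pytest.approx(0.947 * (1 - 0.31 * 7 / 365), abs=1e-12)
    assert q < 0.947


# ------------------------------------------------------- treated outcome

def _p_dead(tree):
    return sum(p for _, p, payoff in enumerate_paths(tree) if payoff.effectiveness == 0.0)


def test_direct_mortality_reads_through(base_params, plain_structure):
    sub = treated_outcome(base_params, plain_structure, 0.0, empiric=True)
    assert _p_dead(sub) == pytest.approx(0.135, abs=1e-12)


def test_success_mediated_mortality_hand_value(base_params):
    s = StructureConfig(mortality_mode="success_mediated", sepsis_dw_applied=False)
    sub = treated_outcome(base_params, s, 0.0, empiric=True)
    # susceptible failures + resistant deaths: 0.935*0.20 + 0.065*0.90
    assert _p_dead(sub) == pytest.approx(0.2455, abs=1e-12)


def test_certain_success_means_no_deaths(base_params):
    s = StructureConfig(mortality_mode="success_mediated", sepsis_dw_applied=False)
    p = base_params.with_value("p_resistance", 0.0).with_value(
        "p_treatment_success_sensitive", 1.0)
    sub = treated_outcome(p, s, 0.0, empiric=True)
    assert _p_dead(sub) == 0.0


def test_empiric_mode_splits_by_arm(base_params, plain_structure):
    s = plain_structure.model_copy(update={"mortality_mode": "empiric_success_mediated"})
    empiric = treated_outcome(base_params, s, 0.0, empiric=True)
    soc = treated_outcome(base_params, s, 0.0, empiric=False)
    assert _p_dead(empiric) == pytest.approx(0.2455, abs=1e-12)
    assert _p_dead(soc) == pytest.approx(0.135, abs=1e-12)


# ------------------------------------------------------------ treat all

def test_treat_all_cost_is_diagnostic_plus_treatment_on_every_path(
    base_params, plain_structure
):
    tree = build_treat_all(base_params, "xpert", plain_structure)
    for _, _, payoff in enumerate_paths(tree):
        assert payoff.cost == pytest.approx(17.42 + 195, abs=1e-12)


def test_treat_all_collapses_at_zero_prevalence(base_params, plain_structure):
    p = base_params.with_value("prevalence_tb", 0.0)
    out = rollback(build_treat_all(p, "xpert", plain_structure))
    assert out.effectiveness == pytest.approx(0.8 * 0.947, abs=1e-12)


# ------------------------------------------------------------ selective

def test_selective_treatment_cost_fraction_is_marginal_positivity(
    base_params, plain_structure
):
    """With no delayed empiric therapy, only test-positives are treated."""
    out = rollback(build_selective(base_params, "xpert", plain_structure))
    assert out.cost == pytest.approx(17.42 + 195 * 0.215, abs=1e-9)


def test_perfect_test_removes_the_effectiveness_gap(base_params, plain_structure):
    p = (base_params
         .with_value("diagnostics.xpert.sensitivity", 1.0)
         .with_value("diagnostics.xpert.specificity", 1.0))
    ta = rollback(build_treat_all(p, "xpert", plain_structure))
    soc = rollback(build_selective(p, "xpert", plain_structure))
    assert ta.effectiveness == pytest.approx(soc.effectiveness, rel=1e-12)
    # cost differs only by the treatment averted in true-negative patients
    assert ta.cost - soc.cost == pytest.approx(195 * 0.5, abs=1e-9)


def test_factorizations_are_rollback_equivalent(base_params):
    for delayed in (False, True):
        s1 = StructureConfig(soc_delayed_empiric=delayed, factorization="test_first")
        s2 = StructureConfig(soc_delayed_empiric=delayed, factorization="disease_first")
        for diag in DIAGNOSTICS:
            a = rollback(build_selective(base_params, diag, s1))
            b = rollback(build_selective(base_params, diag, s2))
            assert a.cost == pytest.approx(b.cost, rel=1e-12)
            assert a.effectiveness == pytest.approx(b.effectiveness, rel=1e-12)


def test_unknown_diagnostic_is_a_configuration_error(base_params, plain_structure):
    with pytest.raises(KeyError, match="fujilam"):
        build_treat_all(base_params, "fujilam", plain_structure)
    with pytest.raises(ValueError, match="unknown arm"):
        expected_outcomes(base_params, "xpert", "both", plain_structure)


# ------------------------------------------------- whole-model invariants

@pytest.mark.parametrize("mode", ["mortality_direct", "success_mediated",
                                  "empiric_success_mediated"])
@pytest.mark.parametrize("delayed", [False, True])
def test_all_six_arms_validate_and_match_enumeration(base_params, mode, delayed):
    s = StructureConfig(mortality_mode=mode, soc_delayed_empiric=delayed)
    for diag in DIAGNOSTICS:
        for builder in (build_treat_all, build_selective):
            tree = builder(base_params, diag, s)
            assert validate(tree) == []
            rb = rollback(tree)
            en = expected_payoff_by_enumeration(tree)
            assert math.isclose(rb.cost, en.cost, rel_tol=1e-12)
            assert math.isclose(rb.effectiveness, en.effectiveness, rel_tol=1e-12)


def test_incremental_effectiveness_nonincreasing_in_sensitivity(
    base_params, plain_structure
):
    """Better case detection shrinks the missed-TB pool that empiric
    therapy rescues, so the treat-all advantage falls with sensitivity."""
    deltas = []
    for sens in (0.42, 0.535, 0.635, 0.8, 0.95):
        p = base_params.with_value("diagnostics.xpert.sensitivity", sens)
        ta = expected_outcomes(p, "xpert", "treat_all", plain_structure)
        soc = expected_outcomes(p, "xpert", "selective", plain_structure)
        deltas.append(ta.effectiveness - soc.effectiveness)
    assert all(a >= b - 1e-12 for a, b in zip(deltas, deltas[1:]))
    assert all(d >= 0 for d in deltas)


def test_equal_mortality_and_utility_zeroes_the_increment(base_params):
    s = StructureConfig(soc_delayed_empiric=False, sepsis_dw_applied=False)
    p = (base_params
         .with_value("p_death_untreated_tb", 0.135)
         .with_value("dw_tb_hiv", base_params.dw_tb_treatment.value))
    ta = expected_outcomes(p, "xpert", "treat_all", s)
    soc = expected_outcomes(p, "xpert", "selective", s)
    assert ta.effectiveness - soc.effectiveness == pytest.approx(0.0, abs=1e-12)
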