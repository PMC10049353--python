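"""Bayesian layer for diagnostic test outcomes.

Given disease prevalence and a test's sensitivity/specificity, these
functions return the marginal probability of a positive result and the
posterior disease probabilities (PPV, NPV) that parameterise the
selective-treatment arm's branches.  The two tree factorisations —
test-result-first (marginal + posteriors) and disease-first (prevalence +
conditional test results) — are mathematically equivalent under rollback;
this module supplies the quantities for either.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal

__all__ = [
    "DiagnosticProfile",
    "UndefinedPosteriorError",
    "prob_test_positive",
    "ppv",
    "npv",
    "p_disease_given_negative",
    "compose",
]


class UndefinedPosteriorError(ZeroDivisionError):
    """The conditioning event has probability zero, so the posterior is undefined."""


@dataclass(frozen=True)
class DiagnosticProfile:
    """One test: sensitivity, specificity and per-test unit cost (USD)."""

    name: str
    sensitivity: float
    specificity: float
    unit_cost: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.sensitivity <= 1.0:
            raise ValueError(f"sensitivity must be in [0, 1], got {self.sensitivity}")
        if not 0.0 <= self.specificity <= 1.0:
            raise ValueError(f"specificity must be in [0, 1], got {self.specificity}")
        if self.unit_cost < 0:
            raise ValueError(f"unit_cost must be >= 0, got {self.unit_cost}")
        # costs may arrive as Decimal from the parameter file; store float
        object.__setattr__(self, "unit_cost", float(self.unit_cost))


def _check_prevalence(prevalence: float) -> float:
    if not 0.0 <= prevalence <= 1.0:
        raise ValueError(f"prevalence must be in [0, 1], got {prevalence}")
    return float(prevalence)


def prob_test_positive(prevalence: float, test: DiagnosticProfile) -> float:
    """Marginal P(test+) = prev * sens + (1 - prev) * (1 - spec)."""
    prevalence = _check_prevalence(prevalence)
    return prevalence * test.sensitivity + (1.0 - prevalence) * (1.0 - test.specificity)


def ppv(prevalence: float, test: DiagnosticProfile) -> float:
    """Positive predictive value P(disease | test+) via Bayes' rule."""
    prevalence = _check_prevalence(prevalence)
    p_pos = prob_test_positive(prevalence, test)
    if p_pos == 0.0:
        raise UndefinedPosteriorError(
            f"P(test+) = 0 for {test.name}; PPV undefined"
        )
    return prevalence * test.sensitivity / p_pos


def npv(prevalence: float, test: DiagnosticProfile) -> float:
    """Negative predictive value P(no disease | test-) via Bayes' rule."""
    prevalence = _check_prevalence(prevalence)
    p_neg = 1.0 - prob_test_positive(prevalence, test)
    if p_neg == 0.0:
        raise UndefinedPosteriorError(
            f"P(test-) = 0 for {test.name}; NPV undefined"
        )
    return (1.0 - prevalence) * test.specificity / p_neg


def p_disease_given_negative(prevalence: float, test: DiagnosticProfile) -> float:
    """P(disease | test-) = 1 - NPV; parameterises the missed-disease branch."""
    return 1.0 - npv(prevalence, test)


def compose(
    a: DiagnosticProfile,
    b: DiagnosticProfile,
    name: str = "combined",
    rule: str = "either-positive",
) -> DiagnosticProfile:
    """Compose two tests under an independence assumption (exploratory only).

    With ``rule="either-positive"`` the combination is positive when either
    test is: sens = 1 - (1-sens_a)(1-sens_b), spec = spec_a * spec_b, cost =
    sum of unit costs.  The case-study combined LAM+Xpert strategy does *not*
    use this: its tabulated sensitivity (63.5%) comes from literature
    estimates and is lower than the independence composition (~72.7%),
    because the two tests' detection failures are correlated in practice.
    """
    if rule != "either-positive":
        raise ValueError(f"unknown composition rule {rule!r}")
    return DiagnosticProfile(
        name=name,
        sensitivity=1.0 - (1.0 - a.sensitivity) * (1.0 - b.sensitivity),
        specificity=a.specificity * b.specificity,
        unit_cost=float(Decimal(str(a.unit_cost)) + Decimal(str(b.unit_cost))),
    )
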