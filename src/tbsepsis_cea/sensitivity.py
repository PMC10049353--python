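"""One-way deterministic sensitivity analysis (tornado diagrams).

Each parameter is moved to the ends of its published range — or, when no
range exists, to +/-10% of its base value (multiplicative, clipped to [0, 1]
for probabilities and disability weights) — while every other parameter is
held at base.  The outcome is the incremental effectiveness (QALY
difference between treat-all and selective treatment) or the ICER for one
diagnostic strategy.  The spread |outcome(high) - outcome(low)| is the bar
length of the tornado diagram row.

By default only parameters carrying an explicit range are varied, matching
an input table in which ranges mark membership in the sensitivity analysis;
further parameters can be included by name (the +/-10% rule then applies).
Probabilities always appear in complementary (p, 1-p) branch pairs in the
built trees, so the sibling branch absorbs the excursion automatically.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

from .cea import icer as _icer
from .parameters import PROBABILITY_FIELDS, ParameterSet, StructureConfig
from .trial import expected_outcomes

__all__ = ["TornadoEntry", "one_way", "tornado", "write_tornado_csv", "plot_tornado"]


@dataclass(frozen=True)
class TornadoEntry:
    """One row of a tornado diagram."""

    parameter: str
    base_value: float
    low_value: float
    high_value: float
    outcome_at_base: float
    outcome_at_low: float
    outcome_at_high: float

    @property
    def spread(self) -> float:
        return abs(self.outcome_at_high - self.outcome_at_low)


def _outcome(
    params: ParameterSet, structure: StructureConfig, diagnostic: str, outcome: str
) -> float:
    treat_all = expected_outcomes(params, diagnostic, "treat_all", structure)
    soc = expected_outcomes(params, diagnostic, "selective", structure)
    if outcome == "delta_qaly":
        return treat_all.effectiveness - soc.effectiveness
    if outcome == "icer":
        res = _icer(treat_all, soc)
        if res.icer is None:
            raise ValueError(
                f"ICER undefined for {diagnostic} ({res.dominance}); "
                "use the delta_qaly outcome"
            )
        return res.icer
    raise ValueError(f"unknown outcome {outcome!r}; expected 'delta_qaly' or 'icer'")


def _excursions(
    params: ParameterSet, name: str, pct: float, additive: bool
) -> tuple[float, float, float]:
    base = params.value_of(name)
    rng = params.range_of(name)
    if rng is not None:
        low, high = rng  # a zero-width range stays degenerate (warned below)
    else:
        if additive:
            low, high = base - pct, base + pct
        else:
            low, high = base * (1.0 - pct), base * (1.0 + pct)
        is_fraction = name in PROBABILITY_FIELDS or (
            name.startswith("diagnostics.") and not name.endswith("unit_cost")
        )
        if is_fraction:
            low, high = max(0.0, low), min(1.0, high)
        else:
            low = max(0.0, low)
    return base, low, high


def one_way(
    parameter: str,
    params: ParameterSet,
    structure: StructureConfig,
    diagnostic: str,
    outcome: str = "delta_qaly",
    pct: float = 0.10,
    additive: bool = False,
) -> TornadoEntry:
    """Evaluate the outcome at one parameter's low and high excursions.

    ``parameter`` is a scalar field name or a dotted diagnostic field such
    as ``"diagnostics.xpert.sensitivity"``.  When the parameter has no
    published range the +/-10% rule applies (relative by default; additive
    with ``additive=True``), clipped to [0, 1] for fractions.
    """
    base, low, high = _excursions(params, parameter, pct, additive)
    if low == high == base:
        warnings.warn(f"parameter {parameter!r} has a degenerate range; spread is 0")
    at_base = _outcome(params, structure, diagnostic, outcome)
    at_low = _outcome(params.with_value(parameter, low), structure, diagnostic, outcome)
    at_high = _outcome(params.with_value(parameter, high), structure, diagnostic, outcome)
    return TornadoEntry(
        parameter=parameter,
        base_value=base,
        low_value=low,
        high_value=high,
        outcome_at_base=at_base,
        outcome_at_low=at_low,
        outcome_at_high=at_high,
    )


def default_tornado_parameters(params: ParameterSet) -> list[str]:
    """Parameters carrying an explicit sensitivity range, in field order."""
    return [n for n in params.scalar_names() if params.range_of(n) is not None]


def tornado(
    params: ParameterSet,
    structure: StructureConfig,
    diagnostic: str,
    outcome: str = "delta_qaly",
    parameters: Optional[Sequence[str]] = None,
    pct: float = 0.10,
    additive: bool = False,
) -> list[TornadoEntry]:
    """One-way entries for every varied parameter, sorted by descending
    spread (ties broken by parameter name for reproducibility)."""
    names = list(parameters) if parameters is not None else default_tornado_parameters(params)
    entries = [
        one_way(n, params, structure, diagnostic, outcome, pct=pct, additive=additive)
        for n in names
    ]
    entries.sort(key=lambda e: (-e.spread, e.parameter))
    return entries


def write_tornado_csv(entries: Sequence[TornadoEntry], path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(
            ["parameter", "base", "low", "high", "outcome_base",
             "outcome_low", "outcome_high", "spread", "rank"]
        )
        for rank, e in enumerate(entries, start=1):
            w.writerow(
                [e.parameter, repr(e.base_value), repr(e.low_value), repr(e.high_value),
                 repr(e.outcome_at_base), repr(e.outcome_at_low), repr(e.outcome_at_high),
                 repr(e.spread), rank]
            )


def plot_tornado(entries: Sequence[TornadoEntry], path, title: str = "Tornado diagram") -> None:
    """Render a horizontal-bar tornado plot (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    entries = list(entries)[::-1]  # largest spread on top
    fig, ax = plt.subplots(figsize=(8, 0.5 * len(entries) + 1.5))
    for i, e in enumerate(entries):
        lo = min(e.outcome_at_low, e.outcome_at_high)
        hi = max(e.outcome_at_low, e.outcome_at_high)
        ax.barh(i, hi - lo, left=lo, color="#4878a8")
    base = entries[0].outcome_at_base if entries else 0.0
    ax.axvline(base, color="k", lw=1, ls="--")
    ax.set_yticks(range(len(entries)))
    ax.set_yticklabels([e.parameter for e in entries])
    ax.set_xlabel("outcome")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
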