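"""Payer-perspective cost model with quality-of-life adjustment.

A hospitalization costs the payer side ``T`` dollars in total, split into a
hospital-billing component ``H`` and a lost-productivity component ``W``
(lost wages and out-of-pocket costs).  The split is parameterized by a
constant difference ``d``:

    H = (T + d) / 2,    W = (T - d) / 2        (H + W = T, H - W = d)

The at-home program reduces hospital billing by a fraction ``rH`` (base
0.75, stays are mostly avoided) and recovers a fraction ``rW`` of lost
wages (base 0.30; patients remain acutely ill at home), so the with-program
cost is

    C = (1 - rH) * H + (1 - rW) * W

Quality-of-life adjustment divides a cost by the QoL score under which it
is incurred (hospital 0.7-0.75, home 0.85-0.9), giving quality-weighted
dollars.  Two reimbursement questions follow: the payer cost when the
program is reimbursed R per patient, and the neutrality threshold R at
which the payer is indifferent.  Note the orderings differ by design: a
fixed reimbursement is added to the home-care cost *before* QoL division
(it is itself a home-care outlay), whereas the neutrality threshold
equates the two QoL-adjusted sides *after* division:

    unadjusted neutrality:   R = T - C
    QoL-adjusted neutrality: R = T/q0 - C/q1
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from ._money import dollars, percent

__all__ = [
    "PayerCostAssumptions",
    "split_total_cost",
    "payer_cost_with_program",
    "qol_adjust",
    "payer_cost_with_reimbursement",
    "payer_neutrality_reimbursement",
    "savings_percent",
    "payer_table",
]

#: Total-cost sensitivity grid (USD per hospitalization).
TOTAL_COST_GRID: tuple[float, ...] = (20_000, 25_000, 30_000, 35_000, 40_000, 45_000)


@dataclass(frozen=True)
class PayerCostAssumptions:
    """Parameters of the payer-perspective model.

    Parameters
    ----------
    total_cost
        Combined payer cost of one hospitalization (billing + lost
        productivity), USD; modelled between 20,000 and 45,000, base 30,000.
    split_difference
        Constant difference ``H - W`` between the billing and productivity
        components, USD (default 5,000).
    hosp_reduction
        Fraction of hospital billing the program removes (0.60/0.75/0.90).
    wage_recovery
        Fraction of lost wages / out-of-pocket costs recovered (0.15/0.30/0.45).
    qol_hospital, qol_home
        Quality-of-life scores while hospitalized vs at home on the
        program (0 = death, 1 = normal function).
    urgent_care_cost
        Published cost of one urgent-care follow-up visit, USD; carried as
        reporting metadata, not a separate term in the cost arithmetic.
    """

    total_cost: float = 30_000.0
    split_difference: float = 5_000.0
    hosp_reduction: float = 0.75
    wage_recovery: float = 0.30
    qol_hospital: float = 0.7
    qol_home: float = 0.9
    urgent_care_cost: float = 267.0

    def __post_init__(self) -> None:
        if not (0 <= self.hosp_reduction <= 1 and 0 <= self.wage_recovery <= 1):
            raise ValueError("reduction fractions must lie in [0, 1]")
        if not (0 < self.qol_hospital <= self.qol_home <= 1):
            raise ValueError("need 0 < qol_hospital <= qol_home <= 1")
        if not (self.total_cost > self.split_difference >= 0):
            raise ValueError("need total_cost > split_difference >= 0")


def split_total_cost(total_cost: float, split_difference: float = 5_000.0) -> tuple[float, float]:
    """Split total payer cost into (hospital billing, lost productivity)."""
    if not (total_cost > split_difference >= 0):
        raise ValueError("need total_cost > split_difference >= 0")
    hospital = (total_cost + split_difference) / 2.0
    wages = (total_cost - split_difference) / 2.0
    return hospital, wages


def payer_cost_with_program(a: PayerCostAssumptions) -> float:
    """Payer cost per case with the program, before any reimbursement."""
    hospital, wages = split_total_cost(a.total_cost, a.split_difference)
    return (1.0 - a.hosp_reduction) * hospital + (1.0 - a.wage_recovery) * wages


def qol_adjust(cost: float, qol: float) -> float:
    """Express a cost in quality-weighted dollars by dividing by its QoL score."""
    if qol <= 0:
        raise ValueError("QoL score must be positive")
    return cost / qol


def payer_cost_with_reimbursement(
    a: PayerCostAssumptions, reimbursement: float
) -> tuple[float, float]:
    """Payer cost per case when the program is reimbursed R per patient.

    Returns ``(unadjusted, qol_adjusted)``; the reimbursement is part of
    the home-care outlay, so it is added before the QoL division.
    """
    if reimbursement < 0:
        raise ValueError("reimbursement must be >= 0")
    with_program = payer_cost_with_program(a) + reimbursement
    return with_program, qol_adjust(with_program, a.qol_home)


def payer_neutrality_reimbursement(
    a: PayerCostAssumptions, qol_adjusted: bool = False
) -> tuple[float, int]:
    """Reimbursement per patient at which payer costs are neutral.

    Unadjusted: R = T - C.  QoL-adjusted: R = T/q0 - C/q1, equating the
    quality-weighted with- and without-program costs.  Returns ``(R,
    R as integer percent of the matching without-program cost)``.
    """
    with_program = payer_cost_with_program(a)
    if qol_adjusted:
        without = qol_adjust(a.total_cost, a.qol_hospital)
        r = without - qol_adjust(with_program, a.qol_home)
    else:
        without = a.total_cost
        r = without - with_program
    return r, percent(100.0 * r / without)


def savings_percent(cost_with: float, cost_without: float) -> int:
    """Signed percent change of with-program vs without-program cost."""
    if cost_without == 0:
        raise ValueError("cost_without must be nonzero")
    return percent(100.0 * (cost_with / cost_without - 1.0))


def payer_table(
    hosp_reduction: float = 0.75,
    wage_recovery: float = 0.30,
    qol_hospital: float = 0.7,
    qol_home: float = 0.9,
    reimbursement: float = 15_000.0,
    total_cost_grid: tuple[float, ...] = TOTAL_COST_GRID,
    split_difference: float = 5_000.0,
) -> pd.DataFrame:
    """Payer-perspective sensitivity table over the total-cost grid.

    Rows: with-program cost (unadjusted / QoL-adjusted), cost with a fixed
    per-patient reimbursement, and the payer-neutrality reimbursement
    threshold; each cell a rounded dollar value with the percent change
    (or percent-of-cost for thresholds) alongside.
    """
    rows: dict[str, dict[str, str]] = {}
    for total in total_cost_grid:
        a = PayerCostAssumptions(
            total_cost=total,
            split_difference=split_difference,
            hosp_reduction=hosp_reduction,
            wage_recovery=wage_recovery,
            qol_hospital=qol_hospital,
            qol_home=qol_home,
        )
        col = f"{int(total)}"
        c = payer_cost_with_program(a)
        cells = {
            "with_program_unadjusted": (dollars(c), savings_percent(c, total)),
            "with_program_qol": (
                dollars(qol_adjust(c, a.qol_home)),
                savings_percent(qol_adjust(c, a.qol_home), qol_adjust(total, a.qol_hospital)),
            ),
        }
        unadj_r, qol_r = payer_cost_with_reimbursement(a, reimbursement)
        cells["with_reimbursement_unadjusted"] = (
            dollars(unadj_r),
            savings_percent(unadj_r, total),
        )
        cells["with_reimbursement_qol"] = (
            dollars(qol_r),
            savings_percent(qol_r, qol_adjust(total, a.qol_hospital)),
        )
        for flag, label in ((False, "neutrality_unadjusted"), (True, "neutrality_qol")):
            r, pct = payer_neutrality_reimbursement(a, qol_adjusted=flag)
            cells[label] = (dollars(r), pct)
        for label, (value, pct) in cells.items():
            rows.setdefault(label, {})[col] = f"{value} ({pct})"
    return pd.DataFrame(rows).T[[f"{int(t)}" for t in total_cost_grid]]
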