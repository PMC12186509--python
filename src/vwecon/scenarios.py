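"""Payer-mix and variable-cost scenario engine.

Projects the per-patient rate components of the base-case cohort onto
arbitrary payer mixes and enrolment sizes, scales the variable-cost
component for one-way sensitivity analysis, and solves two break-even
problems in closed form:

* the largest commercial-payer share at which a two-class
  (commercial + uninsured) cohort still breaks even, and
* the per-patient program reimbursement that restores hospital cost
  neutrality under a given payer mix, with class-specific reimbursement
  weights (e.g. Medicaid paid at half the commercial/Medicare rate,
  uninsured unpaid).

Everything is linear in enrolment and in each mix fraction, so no
iterative solver is needed; dollars are rounded only at report time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import pandas as pd

from ._money import dollars, round_half_up
from .accounting import PayerClass, RateComponents

__all__ = [
    "PayerMix",
    "NeutralityWeights",
    "VARIABLE_COST_GRID",
    "scale_variable_costs",
    "project_mix",
    "MixProjection",
    "breakeven_commercial_fraction",
    "hospital_neutrality_reimbursement",
]

#: One-way sensitivity grid on the variable-cost component.
VARIABLE_COST_GRID: tuple[float, ...] = (0.5, 0.75, 1.0, 1.25, 1.5)

_MIX_TOL = 1e-9


@dataclass(frozen=True)
class PayerMix:
    """Fractions of admissions by payer class (must sum to 1).

    Tricare/VA patients are conventionally folded into the commercial
    fraction for scenario work.
    """

    fractions: Mapping[PayerClass, float]

    def __post_init__(self) -> None:
        total = sum(self.fractions.values())
        if abs(total - 1.0) > _MIX_TOL:
            raise ValueError(f"mix fractions sum to {total!r}, expected 1")
        if any(f < 0 or f > 1 for f in self.fractions.values()):
            raise ValueError("mix fractions must lie in [0, 1]")

    def __getitem__(self, payer: PayerClass) -> float:
        return self.fractions.get(payer, 0.0)

    @property
    def classes(self) -> list[PayerClass]:
        return [p for p, f in self.fractions.items() if f > 0]


@dataclass(frozen=True)
class NeutralityWeights:
    """Relative per-patient reimbursement weight by payer class.

    The default imputes Medicaid payments at one-half the commercial /
    Medicare reimbursement and no payment for uninsured patients.
    """

    weights: Mapping[PayerClass, float] = field(
        default_factory=lambda: {
            PayerClass.COMMERCIAL: 1.0,
            PayerClass.MEDICARE: 1.0,
            PayerClass.MEDICAID: 0.5,
            PayerClass.UNINSURED: 0.0,
        }
    )

    def __post_init__(self) -> None:
        if any(w < 0 or w > 1 for w in self.weights.values()):
            raise ValueError("weights must lie in [0, 1]")

    def __getitem__(self, payer: PayerClass) -> float:
        return self.weights.get(payer, 0.0)


def scale_variable_costs(
    rates: Mapping[PayerClass, RateComponents], factor: float
) -> dict[PayerClass, RateComponents]:
    """Scale only the variable-cost-avoided component of every class."""
    if factor <= 0:
        raise ValueError("variable-cost factor must be positive")
    return {
        p: RateComponents(
            variable_avoided_pp=r.variable_avoided_pp * factor,
            lost_revenue_pp=r.lost_revenue_pp,
            fixed_pp=r.fixed_pp,
        )
        for p, r in rates.items()
    }


@dataclass(frozen=True)
class MixProjection:
    """Projected nets for one payer mix / enrolment size (full precision)."""

    per_class_net: dict[PayerClass, float]
    n_total: int

    @property
    def total_net(self) -> float:
        return sum(self.per_class_net.values())

    def rounded(self) -> dict[PayerClass, int]:
        return {p: dollars(v) for p, v in self.per_class_net.items()}

    @property
    def total_net_dollars(self) -> int:
        return dollars(self.total_net)


def project_mix(
    rates: Mapping[PayerClass, RateComponents],
    mix: PayerMix,
    n_total: int,
) -> MixProjection:
    """Project per-patient nets onto a payer mix of ``n_total`` patients."""
    if n_total < 0:
        raise ValueError("n_total must be >= 0")
    missing = [p.value for p in mix.classes if p not in rates]
    if missing:
        raise KeyError(f"no per-patient rates for payer class(es): {missing}")
    per_class = {
        p: mix[p] * n_total * rates[p].net_pp for p in mix.fractions
    }
    return MixProjection(per_class_net=per_class, n_total=n_total)


def breakeven_commercial_fraction(
    rates: Mapping[PayerClass, RateComponents],
    factor: float = 1.0,
) -> float:
    """Maximum commercial share of a commercial+uninsured cohort at net zero.

    In the extreme two-class analysis the cohort net per patient is
    ``x * net_comm + (1 - x) * net_unins``; the root is
    ``x = net_unins / (net_unins - net_comm)``.  Requires commercial
    net < 0 < uninsured net at the given variable-cost factor, otherwise
    there is no interior break-even.

    Returns the commercial fraction as a percent, rounded half-up to one
    decimal.
    """
    scaled = scale_variable_costs(rates, factor)
    net_comm = scaled[PayerClass.COMMERCIAL].net_pp
    net_unins = scaled[PayerClass.UNINSURED].net_pp
    if not (net_comm < 0 < net_unins):
        raise ValueError(
            "no break-even in (0, 1): commercial and uninsured nets do not bracket zero"
        )
    x = net_unins / (net_unins - net_comm)
    return round_half_up(100.0 * x, 1)


def hospital_neutrality_reimbursement(
    rates: Mapping[PayerClass, RateComponents],
    mix: PayerMix,
    weights: NeutralityWeights | None = None,
    n_total: int = 1000,
    factor: float = 1.0,
) -> float:
    """Per-patient program reimbursement restoring hospital cost neutrality.

    Solves ``total_net + R * n_total * sum_c weight_c * mix_c = 0`` for the
    reference (weight 1.0) reimbursement R, floored at zero when the cohort
    is already net-saving.  Classes pay ``R * weight_c`` each.
    """
    weights = weights or NeutralityWeights()
    weighted_mix = sum(weights[p] * mix[p] for p in mix.fractions)
    projection = project_mix(scale_variable_costs(rates, factor), mix, n_total)
    deficit = -projection.total_net
    if deficit <= 0:
        return 0.0
    if weighted_mix <= 0:
        raise ValueError("neutrality unreachable: no payer carries reimbursement weight")
    return deficit / (n_total * weighted_mix)


def sensitivity_table(
    rates: Mapping[PayerClass, RateComponents],
    mixes: Mapping[str, PayerMix],
    n_total: int = 1000,
    grid: tuple[float, ...] = VARIABLE_COST_GRID,
) -> pd.DataFrame:
    """Payer-mix x variable-cost sensitivity grid of projected nets.

    One row per (mix, payer) plus a total row per mix; one column per
    variable-cost factor, dollars rounded at this reporting boundary.
    """
    records = []
    for mix_name, mix in mixes.items():
        per_factor = {
            f: project_mix(scale_variable_costs(rates, f), mix, n_total) for f in grid
        }
        for p in mix.fractions:
            records.append(
                {
                    "mix": mix_name,
                    "payer": p.value,
                    "admissions_pct": round_half_up(100 * mix[p], 1),
                    **{f"net_x{f}": dollars(per_factor[f].per_class_net[p]) for f in grid},
                }
            )
        records.append(
            {
                "mix": mix_name,
                "payer": "total",
                "admissions_pct": 100.0,
                **{f"net_x{f}": per_factor[f].total_net_dollars for f in grid},
            }
        )
    return pd.DataFrame(records)
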