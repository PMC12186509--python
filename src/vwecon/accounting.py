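"""Hospital-perspective cohort ledger engine.

Builds per-payer-group financial outcomes for a hospital-at-home program:
variable inpatient costs avoided by shortening stays, inpatient revenue
forgone when admissions are avoided or shortened, and an allocation of the
program's fixed costs (staffing plus durable medical equipment).  The
fundamental identity, enforced everywhere, is

    net = variable_avoided - lost_revenue - fixed_alloc

Group ledgers aggregate to cohort totals, and divide down to per-patient
rates that drive payer-mix scenario projections.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from ._money import dollars

__all__ = [
    "Mechanism",
    "PayerClass",
    "PAYER_CLASSES",
    "CostParameters",
    "GroupLedger",
    "PerPatientRates",
    "RateComponents",
    "allocate_fixed_costs",
    "compute_group_ledger",
    "cohort_totals",
    "per_case_rates",
    "read_ledgers_csv",
    "write_ledgers_csv",
    "ledgers_to_frame",
]


class Mechanism(str, enum.Enum):
    """How a payer reimburses inpatient care (determines lost-revenue rule)."""

    DRG_BASED = "drg_based"
    PER_DIEM = "per_diem"
    FLAT_DAILY_RATE = "flat_daily_rate"
    CAPITATED = "capitated"
    NONE = "none"


class PayerClass(str, enum.Enum):
    """Insurance classes of the study cohort.

    Each class carries its default reimbursement mechanism: Medicare pays
    case rates (DRG), fee-for-service Medicaid pays a flat per diem,
    commercial/Tricare-VA pay negotiated flat daily rates, and uninsured
    patients generate no revenue.  Capitated (per-member-per-month) plans
    also lose nothing when an admission is avoided.
    """

    MEDICARE = "medicare"
    MEDICAID = "medicaid"
    COMMERCIAL = "commercial"
    TRICARE_VA = "tricare_va"
    UNINSURED = "uninsured"

    @property
    def mechanism(self) -> Mechanism:
        return _DEFAULT_MECHANISM[self]


_DEFAULT_MECHANISM = {
    PayerClass.MEDICARE: Mechanism.DRG_BASED,
    PayerClass.MEDICAID: Mechanism.PER_DIEM,
    PayerClass.COMMERCIAL: Mechanism.FLAT_DAILY_RATE,
    PayerClass.TRICARE_VA: Mechanism.FLAT_DAILY_RATE,
    PayerClass.UNINSURED: Mechanism.NONE,
}

PAYER_CLASSES: tuple[PayerClass, ...] = tuple(PayerClass)


@dataclass(frozen=True)
class CostParameters:
    """Hospital cost inputs.

    Parameters
    ----------
    daily_variable_cost
        Average variable cost of one inpatient bed-day (USD/day) — actual
        incurred costs that scale with volume, excluding salaries and
        overhead.
    staffing_cost
        Annual program staffing cost (USD/year).
    dme_total
        Total durable medical equipment cost over the program year (USD).
    """

    daily_variable_cost: float = 2945.0
    staffing_cost: float = 518_000.0
    dme_total: float = 164_547.0

    def __post_init__(self) -> None:
        if self.daily_variable_cost <= 0:
            raise ValueError("daily_variable_cost must be positive")
        if self.staffing_cost < 0 or self.dme_total < 0:
            raise ValueError("fixed cost components must be non-negative")

    @property
    def total_fixed(self) -> float:
        return self.staffing_cost + self.dme_total


@dataclass(frozen=True)
class GroupLedger:
    """Financial accounting row for one payer group.

    ``lost_revenue``, ``variable_avoided`` and ``fixed_alloc`` are stored as
    non-negative magnitudes; the sign convention (losses negative) is applied
    only when rendering tables.  ``net`` always satisfies the ledger
    identity, at full float precision.
    """

    payer: PayerClass | None
    n_patients: int
    days_saved: float
    lost_revenue: float
    variable_avoided: float
    fixed_alloc: float

    def __post_init__(self) -> None:
        if self.n_patients < 0:
            raise ValueError("n_patients must be >= 0")
        for name in ("days_saved", "lost_revenue", "variable_avoided", "fixed_alloc"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0 (store magnitudes)")

    @property
    def net(self) -> float:
        return self.variable_avoided - self.lost_revenue - self.fixed_alloc

    @property
    def net_dollars(self) -> int:
        return dollars(self.net)

    @property
    def net_per_case(self) -> float:
        if self.n_patients == 0:
            raise ZeroDivisionError("net_per_case undefined for empty group")
        return self.net / self.n_patients

    @property
    def net_per_case_dollars(self) -> int:
        return dollars(self.net_per_case)


@dataclass(frozen=True)
class RateComponents:
    """Per-patient dollar components for one payer class."""

    variable_avoided_pp: float
    lost_revenue_pp: float
    fixed_pp: float

    def __post_init__(self) -> None:
        for name in ("variable_avoided_pp", "lost_revenue_pp", "fixed_pp"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def net_pp(self) -> float:
        return self.variable_avoided_pp - self.lost_revenue_pp - self.fixed_pp


# A rate table maps each payer class to its per-patient components.
PerPatientRates = Mapping[PayerClass, RateComponents]


def allocate_fixed_costs(
    total_fixed: float, group_counts: Mapping[PayerClass, int]
) -> dict[PayerClass, int]:
    """Allocate program fixed costs across payer groups per capita.

    Each group receives ``total_fixed * n_g / N`` rounded to whole dollars;
    a largest-remainder correction then guarantees the allocation sums
    exactly to ``total_fixed`` (rounded to whole dollars).

    Raises
    ------
    ValueError
        If ``total_fixed`` is negative or all counts are zero.
    """
    if total_fixed < 0:
        raise ValueError("total_fixed must be >= 0")
    if any(c < 0 for c in group_counts.values()):
        raise ValueError("group counts must be >= 0")
    n_total = sum(group_counts.values())
    if n_total == 0:
        raise ValueError("empty cohort: all group counts are zero")

    exact = {p: total_fixed * c / n_total for p, c in group_counts.items()}
    alloc = {p: dollars(v) for p, v in exact.items()}
    residual = dollars(total_fixed) - sum(alloc.values())
    if residual:
        step = 1 if residual > 0 else -1
        # hand the residual dollars to the groups whose rounded share moved
        # furthest in the opposite direction
        order = sorted(exact, key=lambda p: step * (exact[p] - alloc[p]), reverse=True)
        for p in order[: abs(residual)]:
            alloc[p] += step
    return alloc


def compute_group_ledger(
    payer: PayerClass,
    n_patients: int,
    *,
    days_saved: float | None = None,
    lost_revenue: float,
    variable_avoided: float | None = None,
    daily_variable_cost: float | None = None,
    fixed_alloc: float,
) -> GroupLedger:
    """Build one payer group's ledger row.

    ``variable_avoided`` may be given directly in dollars, or derived as
    ``days_saved * daily_variable_cost``.  When both dollars and days are
    supplied the dollar figure wins and days are kept as descriptive.
    """
    if variable_avoided is None:
        if days_saved is None or daily_variable_cost is None:
            raise ValueError(
                "need either variable_avoided or (days_saved, daily_variable_cost)"
            )
        variable_avoided = days_saved * daily_variable_cost
    return GroupLedger(
        payer=payer,
        n_patients=n_patients,
        days_saved=days_saved if days_saved is not None else 0.0,
        lost_revenue=lost_revenue,
        variable_avoided=variable_avoided,
        fixed_alloc=fixed_alloc,
    )


def cohort_totals(ledgers: Sequence[GroupLedger]) -> GroupLedger:
    """Component-wise sum of group ledgers (payer set to None)."""
    if not ledgers:
        raise ValueError("need at least one ledger")
    return GroupLedger(
        payer=None,
        n_patients=sum(l.n_patients for l in ledgers),
        days_saved=sum(l.days_saved for l in ledgers),
        lost_revenue=sum(l.lost_revenue for l in ledgers),
        variable_avoided=sum(l.variable_avoided for l in ledgers),
        fixed_alloc=sum(l.fixed_alloc for l in ledgers),
    )


def per_case_rates(ledger: GroupLedger) -> RateComponents:
    """Divide a group ledger down to per-patient components, full precision."""
    if ledger.n_patients <= 0:
        raise ValueError("per-case rates need n_patients > 0")
    n = ledger.n_patients
    return RateComponents(
        variable_avoided_pp=ledger.variable_avoided / n,
        lost_revenue_pp=ledger.lost_revenue / n,
        fixed_pp=ledger.fixed_alloc / n,
    )


_CSV_COLUMNS = [
    "payer",
    "n_patients",
    "days_saved",
    "lost_revenue",
    "variable_avoided",
    "fixed_alloc",
    "net",
]


def ledgers_to_frame(ledgers: Iterable[GroupLedger]) -> pd.DataFrame:
    rows = [
        {
            "payer": l.payer.value if l.payer is not None else "total",
            "n_patients": l.n_patients,
            "days_saved": l.days_saved,
            "lost_revenue": l.lost_revenue,
            "variable_avoided": l.variable_avoided,
            "fixed_alloc": l.fixed_alloc,
            "net": l.net,
        }
        for l in ledgers
    ]
    return pd.DataFrame(rows, columns=_CSV_COLUMNS)


def write_ledgers_csv(ledgers: Iterable[GroupLedger], path: str | Path) -> None:
    ledgers_to_frame(ledgers).to_csv(path, index=False)


def read_ledgers_csv(path: str | Path) -> list[GroupLedger]:
    """Read group ledgers from CSV (header required; `net` column ignored,
    recomputed from the identity)."""
    df = pd.read_csv(path)
    missing = set(_CSV_COLUMNS[:-1]) - set(df.columns)
    if missing:
        raise ValueError(f"ledger CSV missing columns: {sorted(missing)}")
    out = []
    for _, row in df.iterrows():
        payer = None if row["payer"] == "total" else PayerClass(row["payer"])
        if payer is None:
            continue
        out.append(
            GroupLedger(
                payer=payer,
                n_patients=int(row["n_patients"]),
                days_saved=float(row["days_saved"]),
                lost_revenue=float(row["lost_revenue"]),
                variable_avoided=float(row["variable_avoided"]),
                fixed_alloc=float(row["fixed_alloc"]),
            )
        )
    return out
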