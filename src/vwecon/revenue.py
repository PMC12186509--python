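"""Patient-level lost-revenue rules by reimbursement mechanism.

When a hospital-at-home program avoids or shortens an inpatient stay, the
hospital forgoes the payment that stay would have earned.  The rule depends
on the payer's mechanism:

* **DRG-based (Medicare)** — payment is a case rate (base rate x DRG
  relative weight) plus a disproportionate-share add-on and a daily per
  diem.  Under the two-midnight convention, a stay that still crosses at
  least 2 midnights keeps its full case-rate payment; only the per-diem
  component is lost on avoided days.  An avoided admission (or one cut
  below 2 midnights) loses the case rate, the add-on, and the per diems.
* **Per diem (fee-for-service Medicaid)** — a flat daily rate; the loss is
  rate x days avoided.
* **Flat daily rate (commercial, Tricare/VA, out-of-plan managed care)** —
  same arithmetic as per diem with a plan-specific rate.
* **Capitated / uninsured** — admissions generate no revenue, so nothing
  is lost.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from .accounting import Mechanism, PayerClass

__all__ = [
    "MedicareRateSchedule",
    "PerDiemRate",
    "PatientEncounter",
    "RateSchedules",
    "lost_revenue_medicare",
    "lost_revenue_per_diem",
    "lost_revenue_zero",
    "patient_lost_revenue",
]

#: Minimum midnights an inpatient stay must cross to retain DRG payment.
TWO_MIDNIGHTS = 2


@dataclass(frozen=True)
class MedicareRateSchedule:
    """DRG-based payment parameters.

    drg payment = base_payment_rate x drg_relative_weight; the
    disproportionate-share add-on and daily per diem are added on top.
    The encounter's own DRG weight overrides ``drg_relative_weight`` when
    present.
    """

    base_payment_rate: float
    drg_relative_weight: float = 1.0
    dsh_addon: float = 0.0
    per_diem: float = 0.0

    def __post_init__(self) -> None:
        if min(self.base_payment_rate, self.dsh_addon, self.per_diem) < 0:
            raise ValueError("rates must be non-negative")
        if self.drg_relative_weight <= 0:
            raise ValueError("drg_relative_weight must be positive")

    def drg_payment(self, weight: float | None = None) -> float:
        w = self.drg_relative_weight if weight is None else weight
        return self.base_payment_rate * w


@dataclass(frozen=True)
class PerDiemRate:
    """Flat daily reimbursement rate (USD/day)."""

    rate: float

    def __post_init__(self) -> None:
        if self.rate < 0:
            raise ValueError("rate must be non-negative")


@dataclass(frozen=True)
class PatientEncounter:
    """One patient's counterfactual vs actual stay.

    ``los_without_program`` is the inpatient stay (midnights crossed) the
    patient would have had; ``los_with_program`` is the stay actually
    incurred under the program (0 when the admission was avoided entirely).
    """

    payer: PayerClass
    los_without_program: int
    los_with_program: int
    admitted_under_program: bool = False
    drg_weight: float | None = None
    flat_rate: float | None = None
    urgent_care_visits: int = 0

    def __post_init__(self) -> None:
        if self.los_without_program < 0 or self.los_with_program < 0:
            raise ValueError("lengths of stay must be >= 0")
        if self.los_with_program > self.los_without_program:
            raise ValueError("los_with_program cannot exceed los_without_program")
        if self.urgent_care_visits < 0:
            raise ValueError("urgent_care_visits must be >= 0")

    @property
    def days_avoided(self) -> int:
        return self.los_without_program - self.los_with_program


#: Per-payer-class schedule table.  Medicare wants a MedicareRateSchedule;
#: per-diem / flat-rate classes want a PerDiemRate.
RateSchedules = Mapping[PayerClass, "MedicareRateSchedule | PerDiemRate"]


def lost_revenue_medicare(
    schedule: MedicareRateSchedule, encounter: PatientEncounter
) -> float:
    """Lost revenue for a Medicare (DRG-paid) encounter.

    A stay retained for >= 2 midnights keeps its DRG payment and add-on;
    only per-diem revenue on the avoided days is lost.  Avoided or
    sub-2-midnight stays lose the case rate, add-on, and per diems.
    """
    if encounter.payer is not PayerClass.MEDICARE:
        raise ValueError("encounter is not Medicare")
    days = encounter.days_avoided
    per_diem_loss = schedule.per_diem * days
    if encounter.los_with_program >= TWO_MIDNIGHTS:
        return per_diem_loss
    if days == 0:
        # stay was short even without the program; nothing changed hands
        return 0.0
    return schedule.drg_payment(encounter.drg_weight) + schedule.dsh_addon + per_diem_loss


def lost_revenue_per_diem(rate: PerDiemRate, days_avoided: float) -> float:
    """Flat daily rate x days avoided."""
    if days_avoided < 0:
        raise ValueError("days_avoided must be >= 0")
    return rate.rate * days_avoided


def lost_revenue_zero(encounter: PatientEncounter) -> float:
    """Capitated or uninsured encounters lose exactly nothing.

    Raises if called for a revenue-bearing mechanism, guarding against
    payer misclassification upstream.
    """
    if encounter.payer.mechanism not in (Mechanism.CAPITATED, Mechanism.NONE):
        raise ValueError(
            f"{encounter.payer.value} bears revenue; zero rule does not apply"
        )
    return 0.0


def patient_lost_revenue(
    encounter: PatientEncounter, schedules: RateSchedules
) -> float:
    """Dispatch to the mechanism-specific lost-revenue rule."""
    mech = encounter.payer.mechanism
    if mech in (Mechanism.CAPITATED, Mechanism.NONE):
        return lost_revenue_zero(encounter)

    if mech is Mechanism.DRG_BASED:
        schedule = schedules.get(encounter.payer)
        if not isinstance(schedule, MedicareRateSchedule):
            raise KeyError(
                f"no DRG rate schedule configured for {encounter.payer.value}"
            )
        return lost_revenue_medicare(schedule, encounter)

    # per-diem and flat-daily-rate mechanisms share the arithmetic; the
    # encounter's own negotiated rate, if any, takes precedence
    if encounter.flat_rate is not None:
        return lost_revenue_per_diem(PerDiemRate(encounter.flat_rate), encounter.days_avoided)
    schedule = schedules.get(encounter.payer)
    if not isinstance(schedule, PerDiemRate):
        raise KeyError(f"no daily rate configured for {encounter.payer.value}")
    return lost_revenue_per_diem(schedule, encounter.days_avoided)
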