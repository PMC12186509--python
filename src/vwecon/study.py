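"""Base-case study inputs: the published program-year cohort ledger.

The first program year enrolled 876 patients at a safety-net hospital.
Group-level dollar figures (lost revenue and variable costs avoided, per
payer class) are inputs to this package; fixed costs are allocated per
capita from the published totals.  These constants seed the default
configuration and every scenario projection.
"""

from __future__ import annotations

from .accounting import (
    CostParameters,
    GroupLedger,
    PayerClass,
    RateComponents,
    allocate_fixed_costs,
    cohort_totals,
    per_case_rates,
)

__all__ = [
    "BASE_COSTS",
    "GROUP_COUNTS",
    "GROUP_LOST_REVENUE",
    "GROUP_VARIABLE_AVOIDED",
    "TOTAL_DAYS_SAVED",
    "base_case_ledgers",
    "base_case_rates",
    "LA_GENERAL_MIX",
    "TYPICAL_US_MIX",
    "HALF_COMMERCIAL_MEDICARE_MIX",
    "NAMED_MIXES",
    "MEAN_DRG_WEIGHT",
    "SD_DRG_WEIGHT",
    "URGENT_CARE_VISITS_PER_PATIENT",
]

BASE_COSTS = CostParameters(
    daily_variable_cost=2945.0,
    staffing_cost=518_000.0,
    dme_total=164_547.0,
)

#: Enrolment by insurance class over the program year.
GROUP_COUNTS: dict[PayerClass, int] = {
    PayerClass.MEDICARE: 121,
    PayerClass.MEDICAID: 676,
    PayerClass.COMMERCIAL: 11,
    PayerClass.TRICARE_VA: 3,
    PayerClass.UNINSURED: 65,
}

#: Inpatient revenue forgone by shortening/avoiding admissions (USD, magnitudes).
GROUP_LOST_REVENUE: dict[PayerClass, float] = {
    PayerClass.MEDICARE: 1_876_585.0,
    PayerClass.MEDICAID: 1_670_311.0,
    PayerClass.COMMERCIAL: 444_152.0,
    PayerClass.TRICARE_VA: 34_256.0,
    PayerClass.UNINSURED: 0.0,
}

#: Variable inpatient costs avoided (USD).
GROUP_VARIABLE_AVOIDED: dict[PayerClass, float] = {
    PayerClass.MEDICARE: 1_469_533.0,
    PayerClass.MEDICAID: 7_861_619.0,
    PayerClass.COMMERCIAL: 166_734.0,
    PayerClass.TRICARE_VA: 48_040.0,
    PayerClass.UNINSURED: 761_348.0,
}

#: Total inpatient bed-days avoided in the base case (descriptive; the
#: per-group dollar figures above are authoritative for the ledger).
TOTAL_DAYS_SAVED = 3504

#: Published cohort-level column totals.  The group cells above are
#: whole-dollar roundings of unpublished full-precision values; their sum
#: differs from the published lost-revenue total by $1, so the published
#: totals are carried as inputs in their own right.
TOTAL_LOST_REVENUE = 4_025_305.0
TOTAL_VARIABLE_AVOIDED = 10_307_274.0

#: Cohort case-mix index distribution (DRG relative weight): mean and SD.
MEAN_DRG_WEIGHT = 1.27
SD_DRG_WEIGHT = 0.66

#: 30-day urgent-care follow-up visits per enrolled patient.
URGENT_CARE_VISITS_PER_PATIENT = 0.61


def base_case_ledgers(costs: CostParameters = BASE_COSTS) -> list[GroupLedger]:
    """Reconstruct the base-case group ledgers from the study inputs.

    Fixed costs are allocated per capita across the five payer groups; net
    falls out of the ledger identity.
    """
    fixed = allocate_fixed_costs(costs.total_fixed, GROUP_COUNTS)
    return [
        GroupLedger(
            payer=p,
            n_patients=GROUP_COUNTS[p],
            days_saved=0.0,
            lost_revenue=GROUP_LOST_REVENUE[p],
            variable_avoided=GROUP_VARIABLE_AVOIDED[p],
            fixed_alloc=fixed[p],
        )
        for p in GROUP_COUNTS
    ]


def base_case_rates(
    costs: CostParameters = BASE_COSTS,
) -> dict[PayerClass, RateComponents]:
    """Per-patient rate components for each payer class, full precision."""
    return {l.payer: per_case_rates(l) for l in base_case_ledgers(costs)}


# ---------------------------------------------------------------------------
# Named payer mixes.  Scenario projections fold Tricare/VA into commercial.
# ---------------------------------------------------------------------------

#: The study hospital's own (safety-net) payer mix.
LA_GENERAL_MIX: dict[PayerClass, float] = {
    PayerClass.COMMERCIAL: 0.016,  # commercial + Tricare/VA
    PayerClass.MEDICARE: 0.138,
    PayerClass.MEDICAID: 0.772,
    PayerClass.UNINSURED: 0.074,
}

#: Inpatient-day payer distribution typical of US hospitals.
TYPICAL_US_MIX: dict[PayerClass, float] = {
    PayerClass.COMMERCIAL: 0.45,
    PayerClass.MEDICARE: 0.35,
    PayerClass.MEDICAID: 0.10,
    PayerClass.UNINSURED: 0.10,
}

#: Half the typical commercial/Medicare frequency, the rest Medicaid and
#: self-pay (the Medicaid/self-pay split implied by the scenario's dollar
#: outcomes).
HALF_COMMERCIAL_MEDICARE_MIX: dict[PayerClass, float] = {
    PayerClass.COMMERCIAL: 0.225,
    PayerClass.MEDICARE: 0.175,
    PayerClass.MEDICAID: 0.40,
    PayerClass.UNINSURED: 0.20,
}

NAMED_MIXES: dict[str, dict[PayerClass, float]] = {
    "la_general": LA_GENERAL_MIX,
    "typical_us": TYPICAL_US_MIX,
    "half_commercial_medicare": HALF_COMMERCIAL_MEDICARE_MIX,
}


def base_case_cohort_total(costs: CostParameters = BASE_COSTS) -> GroupLedger:
    """Component-wise sum of the reconstructed group ledgers.

    Carries a $1 rounding residue against :func:`published_total_ledger`
    (see TOTAL_LOST_REVENUE).
    """
    return cohort_totals(base_case_ledgers(costs))


def published_total_ledger(costs: CostParameters = BASE_COSTS) -> GroupLedger:
    """Cohort total built from the published column totals."""
    return GroupLedger(
        payer=None,
        n_patients=sum(GROUP_COUNTS.values()),
        days_saved=float(TOTAL_DAYS_SAVED),
        lost_revenue=TOTAL_LOST_REVENUE,
        variable_avoided=TOTAL_VARIABLE_AVOIDED,
        fixed_alloc=costs.total_fixed,
    )
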