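"""Synthetic patient-level cohort generator.

Emulates the statistical structure of the study cohort — payer mix, days of
inpatient stay avoided, case-mix (DRG relative weight) distribution, and
urgent-care follow-up frequency — so that the patient-level revenue rules
and the group-ledger accounting can be exercised end-to-end without any
real patient data.

Days saved are drawn from a truncated normal rounded to whole days.
Rounding and truncation shift the realized mean away from the nominal
location parameter, so :func:`calibrate` inverts the analytic expectation
``E[round(max(0, N(mu, sd)))]`` when fitting a cohort to target ledgers.
Day draws use antithetic pairing within each payer class: each normal
deviate is paired with its reflection, which leaves every marginal
distribution untouched but sharply reduces Monte Carlo error in class
means (standard variance-reduction practice for simulation checks).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import norm

from ._money import round_half_up
from .accounting import (
    CostParameters,
    GroupLedger,
    Mechanism,
    PayerClass,
    allocate_fixed_costs,
)
from .revenue import (
    MedicareRateSchedule,
    PatientEncounter,
    PerDiemRate,
    RateSchedules,
    patient_lost_revenue,
)
from . import study

__all__ = [
    "SyntheticCohortSpec",
    "generate_cohort",
    "aggregate",
    "calibrate",
    "default_spec",
    "expected_rounded_days",
    "write_encounters_csv",
    "read_encounters_csv",
]


def _study_mix() -> dict[PayerClass, float]:
    n = sum(study.GROUP_COUNTS.values())
    return {p: c / n for p, c in study.GROUP_COUNTS.items()}


def _default_schedules() -> dict[PayerClass, MedicareRateSchedule | PerDiemRate]:
    # placeholder order-of-magnitude rates; real runs calibrate these to a
    # target ledger (see default_spec / calibrate)
    return {
        PayerClass.MEDICARE: MedicareRateSchedule(
            base_payment_rate=8000.0, drg_relative_weight=1.27,
            dsh_addon=1500.0, per_diem=900.0,
        ),
        PayerClass.MEDICAID: PerDiemRate(600.0),
        PayerClass.COMMERCIAL: PerDiemRate(4000.0),
        PayerClass.TRICARE_VA: PerDiemRate(2000.0),
    }


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Conditions under which a synthetic cohort is drawn.

    ``days_mean`` holds the *nominal* (pre-rounding, pre-truncation)
    location of the days-saved distribution, either one value for every
    class or a per-class mapping; ``expected_rounded_days`` gives the
    realized expectation.  ``exact_quota`` assigns payer classes by
    largest-remainder quota instead of multinomial draw (useful for
    fixture building where sampling error in the mix is unwanted).
    """

    n_patients: int = 876
    mix: Mapping[PayerClass, float] = field(default_factory=_study_mix)
    days_mean: float | Mapping[PayerClass, float] = 4.0
    days_sd: float = 2.0
    drg_weight_mean: float = study.MEAN_DRG_WEIGHT
    drg_weight_sd: float = study.SD_DRG_WEIGHT
    rate_schedules: RateSchedules = field(default_factory=_default_schedules)
    urgent_care_rate: float = study.URGENT_CARE_VISITS_PER_PATIENT
    admit_fraction: float = 0.45
    seed: int = 0
    exact_quota: bool = False

    def __post_init__(self) -> None:
        if self.n_patients < 0:
            raise ValueError("n_patients must be >= 0")
        if self.days_sd <= 0:
            raise ValueError("days_sd must be positive")
        if self.drg_weight_mean <= 0 or self.drg_weight_sd <= 0:
            raise ValueError("DRG weight distribution parameters must be positive")
        if not 0 <= self.admit_fraction <= 1:
            raise ValueError("admit_fraction must lie in [0, 1]")
        total = sum(self.mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"mix fractions sum to {total!r}, expected 1")
        if self.urgent_care_rate < 0:
            raise ValueError("urgent_care_rate must be >= 0")

    def mean_days_for(self, payer: PayerClass) -> float:
        if isinstance(self.days_mean, Mapping):
            return self.days_mean[payer]
        return float(self.days_mean)


def expected_rounded_days(mu: float, sd: float) -> float:
    """Expectation of ``round(max(0, N(mu, sd)))``.

    Sums ``k * P(k - 1/2 < X <= k + 1/2)`` over the positive integers
    (all mass at or below one-half rounds/truncates to zero days).
    """
    k_max = max(1, int(math.ceil(mu + 8 * sd)))
    k = np.arange(1, k_max + 1)
    upper = norm.cdf((k + 0.5 - mu) / sd)
    lower = norm.cdf((k - 0.5 - mu) / sd)
    return float(np.sum(k * (upper - lower)))


def _nominal_mu_for_mean(target_mean: float, sd: float) -> float:
    """Invert expected_rounded_days in mu for a given realized mean."""
    if target_mean < 0:
        raise ValueError("target mean days must be >= 0")
    if target_mean == 0:
        return -10.0 * sd  # essentially all mass truncates to zero
    lo, hi = -10.0 * sd, target_mean + 10.0 * sd
    return float(brentq(lambda m: expected_rounded_days(m, sd) - target_mean, lo, hi))


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of the lognormal with the given arithmetic mean and SD."""
    sigma2 = math.log(1.0 + (sd / mean) ** 2)
    return math.log(mean) - sigma2 / 2.0, math.sqrt(sigma2)


def _assign_payers(spec: SyntheticCohortSpec, rng: np.random.Generator) -> list[PayerClass]:
    classes = list(spec.mix)
    probs = np.array([spec.mix[p] for p in classes], dtype=float)
    if spec.n_patients == 0:
        return []
    if spec.exact_quota:
        exact = probs * spec.n_patients
        counts = np.floor(exact).astype(int)
        short = spec.n_patients - int(counts.sum())
        for i in np.argsort(-(exact - counts))[:short]:
            counts[i] += 1
        assigned = [p for p, c in zip(classes, counts) for _ in range(int(c))]
        rng.shuffle(assigned)
        return assigned
    idx = rng.choice(len(classes), size=spec.n_patients, p=probs / probs.sum())
    return [classes[i] for i in idx]


def _draw_days(
    n: int, mu: float, sd: float, rng: np.random.Generator
) -> np.ndarray:
    """Antithetic truncated-normal day draws, rounded to whole days."""
    half = (n + 1) // 2
    z = rng.standard_normal(half)
    z = np.concatenate([z, -z])[:n]
    raw = mu + sd * z
    days = np.array([max(0, int(round_half_up(x))) for x in raw])
    return days


def generate_cohort(spec: SyntheticCohortSpec) -> list[PatientEncounter]:
    """Draw a synthetic cohort; identical specs yield identical cohorts."""
    rng = np.random.default_rng(spec.seed)
    payers = _assign_payers(spec, rng)
    if not payers:
        return []

    # per-class day draws (antithetic within class)
    by_class: dict[PayerClass, list[int]] = {}
    days_of: dict[int, int] = {}
    for p in dict.fromkeys(payers):
        by_class[p] = [i for i, q in enumerate(payers) if q is p]
    for p, idxs in by_class.items():
        draws = _draw_days(len(idxs), spec.mean_days_for(p), spec.days_sd, rng)
        for i, d in zip(idxs, draws):
            days_of[i] = int(d)

    lmu, lsigma = _lognormal_params(spec.drg_weight_mean, spec.drg_weight_sd)
    weights = rng.lognormal(lmu, lsigma, size=len(payers))
    admitted = rng.random(len(payers)) < spec.admit_fraction
    los_with_if_admitted = rng.integers(1, 4, size=len(payers))
    visits = rng.poisson(spec.urgent_care_rate, size=len(payers))

    encounters = []
    for i, payer in enumerate(payers):
        los_with = int(los_with_if_admitted[i]) if admitted[i] else 0
        encounters.append(
            PatientEncounter(
                payer=payer,
                los_without_program=los_with + days_of[i],
                los_with_program=los_with,
                admitted_under_program=bool(admitted[i]),
                drg_weight=float(weights[i]),
                urgent_care_visits=int(visits[i]),
            )
        )
    return encounters


def aggregate(
    encounters: Sequence[PatientEncounter],
    cost_params: CostParameters,
    schedules: RateSchedules,
) -> list[GroupLedger]:
    """Roll patient encounters up into per-payer group ledgers.

    Lost revenue comes from the patient-level rules; variable costs avoided
    are days avoided times the daily variable cost; fixed costs are
    allocated per capita across the represented classes.
    """
    if not encounters:
        return []
    counts: dict[PayerClass, int] = {}
    days: dict[PayerClass, int] = {}
    lost: dict[PayerClass, float] = {}
    for e in encounters:
        counts[e.payer] = counts.get(e.payer, 0) + 1
        days[e.payer] = days.get(e.payer, 0) + e.days_avoided
        lost[e.payer] = lost.get(e.payer, 0.0) + patient_lost_revenue(e, schedules)
    fixed = allocate_fixed_costs(cost_params.total_fixed, counts)
    return [
        GroupLedger(
            payer=p,
            n_patients=counts[p],
            days_saved=float(days[p]),
            lost_revenue=lost[p],
            variable_avoided=days[p] * cost_params.daily_variable_cost,
            fixed_alloc=float(fixed[p]),
        )
        for p in counts
    ]


def calibrate(
    spec: SyntheticCohortSpec,
    targets: Sequence[GroupLedger],
    cost_params: CostParameters,
) -> SyntheticCohortSpec:
    """Fit the generator to target group ledgers.

    For each target class the per-patient variable cost avoided pins the
    realized mean days (``variable_pp / daily_variable_cost``), whose
    nominal location is recovered by inverting the rounded-truncated-normal
    expectation; the per-patient lost revenue then pins an effective flat
    daily rate (``lost_pp / mean_days``).  Medicare is fitted with a pure
    per-diem schedule (case-rate components zeroed), since only per-patient
    totals — not the within-class split between avoided admissions and
    shortened stays — are recoverable from group ledgers.
    """
    days_mean: dict[PayerClass, float] = {}
    schedules: dict[PayerClass, MedicareRateSchedule | PerDiemRate] = {}
    mix: dict[PayerClass, float] = {}
    n_total = sum(t.n_patients for t in targets)
    if n_total == 0:
        raise ValueError("targets must contain patients")
    for t in targets:
        if t.n_patients == 0:
            raise ValueError("each target class needs n_patients > 0")
        p = t.payer
        mix[p] = t.n_patients / n_total
        var_pp = t.variable_avoided / t.n_patients
        lost_pp = t.lost_revenue / t.n_patients
        mean_days = var_pp / cost_params.daily_variable_cost
        days_mean[p] = _nominal_mu_for_mean(mean_days, spec.days_sd)
        if p.mechanism in (Mechanism.CAPITATED, Mechanism.NONE):
            if lost_pp > 0:
                raise ValueError(f"{p.value} cannot carry lost revenue")
            continue
        if mean_days <= 0:
            if lost_pp > 0:
                raise ValueError(
                    f"infeasible target for {p.value}: lost revenue with zero days"
                )
            rate = 0.0
        else:
            rate = lost_pp / mean_days
        if p.mechanism is Mechanism.DRG_BASED:
            schedules[p] = MedicareRateSchedule(
                base_payment_rate=0.0, drg_relative_weight=1.0,
                dsh_addon=0.0, per_diem=rate,
            )
        else:
            schedules[p] = PerDiemRate(rate)
    return replace(
        spec,
        mix=mix,
        days_mean=days_mean,
        rate_schedules=schedules,
    )


def default_spec(
    n_patients: int = 876,
    seed: int = 0,
    cost_params: CostParameters = study.BASE_COSTS,
    **overrides,
) -> SyntheticCohortSpec:
    """Generator spec calibrated to the base-case study ledgers."""
    raw = SyntheticCohortSpec(n_patients=n_patients, seed=seed, **overrides)
    fitted = calibrate(raw, study.base_case_ledgers(cost_params), cost_params)
    return fitted


# ---------------------------------------------------------------------------
# CSV round-trip for encounters
# ---------------------------------------------------------------------------

_ENCOUNTER_COLUMNS = [
    "payer",
    "los_without_program",
    "los_with_program",
    "admitted_under_program",
    "drg_weight",
    "flat_rate",
    "urgent_care_visits",
]


def write_encounters_csv(encounters: Sequence[PatientEncounter], path: str | Path) -> None:
    rows = [
        {
            "payer": e.payer.value,
            "los_without_program": e.los_without_program,
            "los_with_program": e.los_with_program,
            "admitted_under_program": e.admitted_under_program,
            "drg_weight": "" if e.drg_weight is None else repr(e.drg_weight),
            "flat_rate": "" if e.flat_rate is None else repr(e.flat_rate),
            "urgent_care_visits": e.urgent_care_visits,
        }
        for e in encounters
    ]
    pd.DataFrame(rows, columns=_ENCOUNTER_COLUMNS).to_csv(path, index=False)


def read_encounters_csv(path: str | Path) -> list[PatientEncounter]:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = set(_ENCOUNTER_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"encounter CSV missing columns: {sorted(missing)}")
    out = []
    for _, row in df.iterrows():
        out.append(
            PatientEncounter(
                payer=PayerClass(row["payer"]),
                los_without_program=int(row["los_without_program"]),
                los_with_program=int(row["los_with_program"]),
                admitted_under_program=bool(row["admitted_under_program"]),
                drg_weight=None if pd.isna(row["drg_weight"]) else float(row["drg_weight"]),
                flat_rate=None if pd.isna(row["flat_rate"]) else float(row["flat_rate"]),
                urgent_care_visits=int(row["urgent_care_visits"]),
            )
        )
    return out
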