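"""Synthetic cohort generation, aggregation, and calibration recovery."""

import numpy as np
import pytest

from vwecon import study
from vwecon.accounting import (
    GroupLedger,
    PayerClass,
    allocate_fixed_costs,
    per_case_rates,
)
from vwecon.cohort import (
    SyntheticCohortSpec,
    aggregate,
    calibrate,
    default_spec,
    expected_rounded_days,
    generate_cohort,
    read_encounters_csv,
    write_encounters_csv,
)
from vwecon.revenue import (
    MedicareRateSchedule,
    PatientEncounter,
    PerDiemRate,
    patient_lost_revenue,
)

SCHEDULES = {
    PayerClass.MEDICARE: MedicareRateSchedule(6000.0, 1.2, 800.0, 700.0),
    PayerClass.MEDICAID: PerDiemRate(620.0),
    PayerClass.COMMERCIAL: PerDiemRate(4100.0),
    PayerClass.TRICARE_VA: PerDiemRate(2100.0),
}


class TestGenerateCohort:
    def test_size_and_payer_counts_near_study_mix(self):
        spec = SyntheticCohortSpec(n_patients=876, seed=11)
        cohort = generate_cohort(spec)
        assert len(cohort) == 876
        counts = {p: sum(e.payer is p for e in cohort) for p in PayerClass}
        targets = study.GROUP_COUNTS
        for p, target in targets.items():
            # within ~4 multinomial SDs of the study counts
            frac = target / 876
            sd = np.sqrt(876 * frac * (1 - frac))
            assert abs(counts[p] - target) <= 4 * sd + 1

    def test_empty_cohort(self):
        assert generate_cohort(SyntheticCohortSpec(n_patients=0)) == []

    def test_seeded_determinism(self, tmp_path):
        spec = SyntheticCohortSpec(n_patients=200, seed=42)
        a, b = generate_cohort(spec), generate_cohort(spec)
        assert a == b
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        write_encounters_csv(a, p1)
        write_encounters_csv(b, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_different_seeds_differ(self):
        a = generate_cohort(SyntheticCohortSpec(n_patients=200, seed=1))
        b = generate_cohort(SyntheticCohortSpec(n_patients=200, seed=2))
        assert a != b

    def test_exact_quota_mode_hits_counts_exactly(self):
        spec = SyntheticCohortSpec(n_patients=876, seed=3, exact_quota=True)
        cohort = generate_cohort(spec)
        counts = {p: sum(e.payer is p for e in cohort) for p in PayerClass}
        assert counts == study.GROUP_COUNTS

    def test_days_saved_non_negative_and_near_mean(self):
        spec = SyntheticCohortSpec(n_patients=2000, seed=5)
        cohort = generate_cohort(spec)
        days = np.array([e.days_avoided for e in cohort])
        assert (days >= 0).all()
        assert np.mean(days) == pytest.approx(expected_rounded_days(4.0, 2.0), abs=0.15)

    def test_drg_weights_match_target_moments(self):
        spec = SyntheticCohortSpec(n_patients=20_000, seed=9)
        w = np.array([e.drg_weight for e in generate_cohort(spec)])
        assert np.mean(w) == pytest.approx(study.MEAN_DRG_WEIGHT, rel=0.03)
        assert np.std(w) == pytest.approx(study.SD_DRG_WEIGHT, rel=0.12)

    def test_urgent_care_rate(self):
        spec = SyntheticCohortSpec(n_patients=10_000, seed=13)
        visits = [e.urgent_care_visits for e in generate_cohort(spec)]
        assert np.mean(visits) == pytest.approx(0.61, abs=0.03)


class TestAggregate:
    def test_hand_built_cohort_matches_manual_summation(self):
        cohort = [
            PatientEncounter(PayerClass.MEDICARE, 4, 0),     # avoided: full DRG loss
            PatientEncounter(PayerClass.MEDICARE, 6, 3),     # kept >=2: per-diem only
            PatientEncounter(PayerClass.MEDICAID, 5, 0),
            PatientEncounter(PayerClass.MEDICAID, 2, 1),
            PatientEncounter(PayerClass.COMMERCIAL, 3, 0),
            PatientEncounter(PayerClass.TRICARE_VA, 2, 0),
            PatientEncounter(PayerClass.UNINSURED, 7, 0),
            PatientEncounter(PayerClass.UNINSURED, 0, 0),
            PatientEncounter(PayerClass.MEDICAID, 4, 2),
            PatientEncounter(PayerClass.MEDICARE, 5, 5),
        ]
        costs = study.BASE_COSTS
        ledgers = {l.payer: l for l in aggregate(cohort, costs, SCHEDULES)}

        # brute-force oracle over the ten records
        exp_days = {}
        exp_lost = {}
        counts = {}
        for e in cohort:
            counts[e.payer] = counts.get(e.payer, 0) + 1
            exp_days[e.payer] = exp_days.get(e.payer, 0) + e.days_avoided
            exp_lost[e.payer] = exp_lost.get(e.payer, 0.0) + patient_lost_revenue(e, SCHEDULES)
        fixed = allocate_fixed_costs(costs.total_fixed, counts)
        for p, l in ledgers.items():
            assert l.n_patients == counts[p]
            assert l.days_saved == exp_days[p]
            assert l.lost_revenue == pytest.approx(exp_lost[p])
            assert l.variable_avoided == pytest.approx(exp_days[p] * 2945.0)
            assert l.fixed_alloc == fixed[p]
            assert l.net == pytest.approx(
                l.variable_avoided - l.lost_revenue - l.fixed_alloc
            )

    def test_all_uninsured_cohort_loses_nothing(self):
        cohort = [PatientEncounter(PayerClass.UNINSURED, 5, 0) for _ in range(20)]
        (ledger,) = aggregate(cohort, study.BASE_COSTS, {})
        assert ledger.lost_revenue == 0
        assert ledger.variable_avoided == 20 * 5 * 2945.0

    def test_zero_days_everywhere_nets_minus_fixed(self):
        cohort = [PatientEncounter(PayerClass.MEDICAID, 2, 2) for _ in range(10)]
        (ledger,) = aggregate(cohort, study.BASE_COSTS, SCHEDULES)
        assert ledger.variable_avoided == 0
        assert ledger.net == pytest.approx(-study.BASE_COSTS.total_fixed)

    def test_generated_cohort_satisfies_ledger_identity(self):
        spec = default_spec(n_patients=500, seed=21)
        ledgers = aggregate(generate_cohort(spec), study.BASE_COSTS, spec.rate_schedules)
        for l in ledgers:
            assert l.net == pytest.approx(l.variable_avoided - l.lost_revenue - l.fixed_alloc)
            assert l.lost_revenue >= 0


class TestCalibrate:
    def test_medicaid_rate_matches_closed_form(self):
        spec = SyntheticCohortSpec()
        fitted = calibrate(spec, study.base_case_ledgers(), study.BASE_COSTS)
        target = per_case_rates(
            {l.payer: l for l in study.base_case_ledgers()}[PayerClass.MEDICAID]
        )
        mean_days = target.variable_avoided_pp / 2945.0
        assert fitted.rate_schedules[PayerClass.MEDICAID].rate == pytest.approx(
            target.lost_revenue_pp / mean_days
        )

    def test_zero_lost_revenue_gives_zero_rate(self):
        targets = [GroupLedger(PayerClass.MEDICAID, 100, 400.0, 0.0, 400 * 2945.0, 0.0)]
        fitted = calibrate(SyntheticCohortSpec(), targets, study.BASE_COSTS)
        assert fitted.rate_schedules[PayerClass.MEDICAID].rate == 0.0

    def test_infeasible_target_rejected(self):
        targets = [GroupLedger(PayerClass.MEDICAID, 100, 0.0, 5000.0, 0.0, 0.0)]
        with pytest.raises(ValueError, match="infeasible"):
            calibrate(SyntheticCohortSpec(), targets, study.BASE_COSTS)

    def test_nominal_mu_inverts_rounded_truncated_mean(self):
        fitted = default_spec()
        for p, mu in fitted.days_mean.items():
            target = per_case_rates(
                {l.payer: l for l in study.base_case_ledgers()}[p]
            ).variable_avoided_pp / 2945.0
            assert expected_rounded_days(mu, fitted.days_sd) == pytest.approx(target, abs=1e-6)

    def test_recovery_within_two_percent_at_10000(self):
        """Law-of-large-numbers check: re-aggregating a calibrated cohort at
        n=10,000 recovers every class's per-patient lost revenue and
        variable cost avoided within 2%."""
        spec = default_spec(n_patients=10_000, seed=7)
        ledgers = aggregate(generate_cohort(spec), study.BASE_COSTS, spec.rate_schedules)
        targets = {l.payer: per_case_rates(l) for l in study.base_case_ledgers()}
        for l in ledgers:
            got = per_case_rates(l)
            t = targets[l.payer]
            if t.variable_avoided_pp:
                assert got.variable_avoided_pp == pytest.approx(
                    t.variable_avoided_pp, rel=0.02
                )
            if t.lost_revenue_pp:
                assert got.lost_revenue_pp == pytest.approx(t.lost_revenue_pp, rel=0.02)
            else:
                assert got.lost_revenue_pp == 0


def test_encounter_csv_round_trip(tmp_path):
    cohort = generate_cohort(default_spec(n_patients=50, seed=4))
    path = tmp_path / "cohort.csv"
    write_encounters_csv(cohort, path)
    assert read_encounters_csv(path) == cohort


def test_spec_validation():
    with pytest.raises(ValueError):
        SyntheticCohortSpec(days_sd=0)
    with pytest.raises(ValueError):
        SyntheticCohortSpec(mix={PayerClass.MEDICARE: 0.6})
    with pytest.raises(ValueError):
        SyntheticCohortSpec(n_patients=-1)
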