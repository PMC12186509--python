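# vwecon

Health-economic modelling of **all-virtual hospital-at-home ("virtual
ward") acute care** from both the hospital's and the payer's perspective.

Virtual-ward programs discharge acutely ill but stable patients home with
oral/inhalational therapy, remote vital-sign monitoring and daily virtual
visits, in lieu of inpatient care. Whether such a program saves or loses a
hospital money turns almost entirely on *who pays for the beds it empties*:
avoided bed-days save variable cost but also forgo inpatient revenue, and
the revenue rule differs sharply by payer. `vwecon` implements that
accounting as a reusable, tested package for hospital finance and health
services researchers evaluating budget impact of at-home acute care.

## The model

**Hospital perspective.** For each payer group *g* with *n_g* enrolled
patients, the net financial outcome is the ledger identity

```
net_g = variable_avoided_g − lost_revenue_g − fixed_g
```

where `variable_avoided` is avoided bed-days × the hospital's daily
variable cost (base $2,945/bed-day), `fixed` is a per-capita share of the
program's fixed costs (staffing $518,000/yr + durable medical equipment
$164,547, allocated `F·n_g/N` with a largest-remainder correction), and
`lost_revenue` follows the payer's reimbursement mechanism:

| mechanism | payers | rule |
|---|---|---|
| DRG case rate | Medicare | stays kept ≥ 2 midnights retain `base × DRG weight + DSH`; avoided/short stays lose it, plus per-diem × days avoided |
| flat per diem | FFS Medicaid | rate × days avoided |
| flat daily rate | commercial, Tricare/VA | plan rate × days avoided |
| capitation / none | in-plan managed care, uninsured | zero |

Per-patient rates derived from a cohort ledger project linearly onto any
payer mix and enrolment size; the engine solves in closed form the
**break-even commercial fraction** of a two-class (commercial + uninsured)
cohort, `x* = net_unins / (net_unins − net_comm)`, and the **cost-neutral
program reimbursement** `R = deficit / (n · Σ_c w_c·mix_c)` with
class reimbursement weights *w* (Medicaid ½, uninsured 0 by default).

**Payer perspective.** A hospitalization costs the payer side *T*
(billing *H* + lost productivity *W*, split `H−W = $5,000`); the program
reduces billing by `rH` (base 75%) and recovers `rW` of lost wages (base
30%), so `C = (1−rH)H + (1−rW)W`. Quality-of-life adjustment divides
costs by the QoL score under which they accrue (hospital 0.7–0.75, home
0.85–0.9). Neutral reimbursement is `T − C` unadjusted, or
`T/q0 − C/q1` quality-adjusted.

A **synthetic cohort generator** draws patient-level encounters (payer mix,
truncated-normal days saved, lognormal DRG weights, Poisson urgent-care
follow-ups) and can calibrate its rates to any target ledger, so the
patient-level rules and group accounting are testable end-to-end.

## Worked example

The base-case cohort (876 patients at a safety-net hospital) from the
built-in study inputs:

```sh
$ vwecon ledger
     payer  n_patients  days_saved  lost_revenue  variable_avoided  fixed_alloc       net
  medicare         121         0.0     1876585.0         1469533.0        94279 -501331.0
  medicaid         676         0.0     1670311.0         7861619.0       526714 5664594.0
commercial          11         0.0      444152.0          166734.0         8571 -285989.0
tricare_va           3         0.0       34256.0           48040.0         2337   11447.0
 uninsured          65         0.0           0.0          761348.0        50646  710702.0
     total         876         0.0     4025304.0        10307274.0       682547 5599423.0
```

The program nets the hospital ≈ $5.6M ($6,392 per patient) — but only
because 84.6% of patients are Medicaid/uninsured. It loses $4,143 per
Medicare and $25,999 per commercial patient, so under a typical US payer
mix (45% commercial / 35% Medicare) the same program on 1,000 patients
loses ~$11.2M. The reimbursement that restores hospital neutrality, and
the largest commercial share a two-class cohort tolerates:

```sh
$ vwecon neutrality --scale 0.5,1.0,1.5
 variable_cost_factor  reimbursement_per_patient
                  0.5                      21084
                  1.0                      13198
                  1.5                       5312

$ vwecon breakeven --scale 0.5,1.0
 variable_cost_factor  commercial_pct  uninsured_pct
                  0.5            13.1           86.9
                  1.0            29.6           70.4
```

i.e. at base variable costs a $13,198 per-patient program payment
(half-weighted for Medicaid, none for uninsured) makes the typical-mix
hospital whole, and an unreimbursed program breaks even only below a
29.6% commercial share. On the payer side the program cuts per-case
costs by 55–58% (e.g. $20,000 → $8,375), more after QoL adjustment.

Other commands: `vwecon mix-scenarios`, `vwecon payer-costs`,
`vwecon simulate` (synthetic cohorts), `vwecon reproduce-paper`
(all result tables + a run manifest). All accept a YAML `--config`.

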