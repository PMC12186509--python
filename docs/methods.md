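# Methods

## Scope and structure

`vwecon` is a deterministic cost-consequence / budget-impact model of an
all-virtual hospital-at-home program, evaluated from two perspectives:

* **hospital**: avoided variable costs vs forgone inpatient revenue and
  program fixed costs, per payer group (`vwecon.accounting`,
  `vwecon.revenue`), with payer-mix / variable-cost sensitivity and
  break-even solvers (`vwecon.scenarios`);
* **payer**: per-case cost with and without the program, quality-of-life
  weighting, and reimbursement-neutrality thresholds (`vwecon.payer`).

A stochastic synthetic-cohort generator (`vwecon.cohort`) exists solely to
exercise the patient-level revenue rules and the aggregation path; the
headline results are closed-form.

The model deliberately excludes: estimation of days saved from patient
records (length-of-stay effects are an input), charge-to-cost ratio
modelling, bed-backfill revenue from freed capacity (a conservative,
worst-case choice for the hospital), CPI adjustment of literature costs
(inputs are taken as already adjusted), and any QALY life-year accounting
(QoL scores scale costs only).

## Hospital-perspective assumptions

* **Ledger identity.** `net = variable_avoided − lost_revenue −
  fixed_alloc`, enforced per group and in totals. Losses are stored as
  non-negative magnitudes; the negative sign is presentation only.
* **Fixed-cost allocation** is per-capita: group *g* receives
  `round(F·n_g/N)` with a largest-remainder correction so allocations sum
  exactly to *F*. The base-case study ledger confirms this rule: the
  published per-group fixed cells are exactly `682,547 × n_g / 876`
  rounded.
* **Variable cost** defaults to $2,945 per bed-day — the hospital-wide
  average of incurred (not charged) variable costs. When a ledger supplies
  both bed-days and dollars, dollars win; the published per-group dollar
  figures embed sub-day precision that day counts cannot reproduce.
* **Lost-revenue rules.** Medicare: a stay kept ≥ 2 midnights (integer
  midnights-crossed convention) retains its DRG case payment and DSH
  add-on, losing only `per_diem × days_avoided`; an avoided or
  sub-2-midnight stay loses case rate + add-on + per diems. The paper
  trail for the retained-stay case states only that DRG payment is kept;
  modelling the residual as a per-diem loss is our reading, and setting
  `per_diem = 0` recovers the strict no-loss interpretation. FFS Medicaid
  and commercial/Tricare-VA lose a flat daily rate × days avoided.
  Capitated and uninsured encounters lose exactly zero — calling the zero
  rule on a revenue-bearing class is an error, to catch misclassification.
  Rate-schedule dollar values are configuration inputs, not constants.
* **Known input inconsistencies.** The published base-case group cells are
  whole-dollar roundings: summing them gives total lost revenue 4,025,304
  vs the published column total 4,025,305, hence a component-sum total net
  of 5,599,423 vs the published 5,599,422. Both are carried:
  `cohort_totals` is always the exact component sum, while
  `study.published_total_ledger()` holds the published totals row as data.
  Similarly the published grand total of the safety-net-mix scenario
  column differs from the sum of its own cells by $181; we report the sum.

## Scenario engine

Projections are linear: per-class net = `mix_fraction × n ×
per-patient net`, with per-patient rates kept at full precision (no
intermediate rounding) and Tricare/VA folded into the commercial
head-count (commercial rates apply; the class is 0.3% of the cohort).
The variable-cost factor grid {0.5, 0.75, 1.0, 1.25, 1.5} scales only the
variable-avoided component. Because the model is linear, both solvers are
closed-form:

* break-even commercial fraction `x* = net_unins/(net_unins − net_comm)`,
  reported in percent, half-up to one decimal, defined only when the two
  class nets bracket zero;
* neutrality reimbursement `R = max(0, −total_net)/(n·Σ w_c·mix_c)` with
  default weights commercial = Medicare = 1, Medicaid = ½, uninsured = 0.
  `R = 0` when the cohort is already net-saving; an all-zero weighted mix
  with a deficit raises "neutrality unreachable".

The named scenario `half_commercial_medicare` uses Medicaid 40% /
uninsured 20%: those are the fractions its published per-class dollar
outcomes imply, although the scenario's percent labels were printed as
30/30.

## Payer-perspective assumptions

Total per-hospitalization payer cost *T* (grid $20k–$45k, base $30k)
splits into hospital billing and lost productivity with a constant
difference `H − W = $5,000`. This computational rule reproduces every
published with-program and neutrality cell across all six *T* values and
all three assumption sets; the narrative component estimates
($16,900/$13,300, which sum to $30,200, not $30,000) motivate the base
case but are not the table arithmetic. Urgent-care follow-up costs
($213–$321/visit at 0.61 visits/patient) are carried as metadata and
contribute no separate term, matching the published cells.

Reimbursement/QoL ordering differs by question, intentionally: a fixed
per-patient reimbursement is a home-care outlay, so it is added *before*
dividing by the home QoL score; the neutrality threshold equates the two
QoL-adjusted sides, so it is the difference of the *divided* costs
(`T/q0 − C/q1`). Both orderings are explicit in the API. One published
sensitivity row (90%/45% effect sizes with QoL 0.7 vs 0.9) is internally
inconsistent with this formula — it matches `(T − C)/0.7`, dividing both
sides by the hospital score — and is not reproduced.

## Synthetic cohort generator

The generator emulates the study conditions: 876 patients; payer mix
13.8% Medicare / 77.2% Medicaid / 1.3% commercial / 0.3% Tricare-VA /
7.4% uninsured; days saved per patient from a truncated normal (mean ≈ 4,
SD 2, default) rounded to whole days; DRG relative weights lognormal with
arithmetic mean 1.27 and SD 0.66; urgent-care follow-ups Poisson(0.61);
45% of encounters begin as inpatient admissions later shortened. Payer
assignment is a seeded multinomial draw so sampling-error tests are
meaningful; an exact-quota mode exists for fixture building. Identical
spec + seed reproduces byte-identical cohorts.

Numerical details that matter:

* Rounding and truncation bias the realized mean of
  `round(max(0, N(μ, σ)))` away from μ, so **calibration inverts the
  analytic expectation** (a finite sum of normal-CDF differences, solved
  by bisection) rather than using μ directly.
* Day draws use **antithetic pairing** within each payer class (each
  normal deviate paired with its reflection). Marginal distributions are
  unchanged; the Monte Carlo error of class means shrinks enough that the
  2%-recovery check below has adequate power even for the 0.3%-share
  Tricare/VA class at n = 10,000.
* `calibrate` fits, per revenue-bearing class, mean days =
  `variable_pp / daily_variable_cost` and an **effective flat daily
  rate** = `lost_pp / mean_days`; for Medicare the case-rate components
  are zeroed, because group ledgers identify only per-patient totals, not
  the split between avoided admissions and shortened stays. Targets
  implying lost revenue with zero days are rejected as infeasible.

Encounters carry only financially active fields; demographic covariates
would add surface without exercising any rule.

What passing the simulation tests does **not** show: the generator imposes
independence across patients, a common days-saved dispersion for all
classes (only the mean is class-specific), and an effective-per-diem
Medicare loss; real claims data have correlated case mix, payer-specific
length-of-stay distributions, and DRG-boundary effects the calibration
deliberately averages out.

## Numerical conventions

All currency is computed in double precision and rounded only at
reporting boundaries, half away from zero to whole dollars (percentages to
one decimal for mix fractions, integers elsewhere). Payer-mix fractions
must sum to 1 within 1e-9. Problem sizes used in tests and the acceptance
script — 1,000-patient projections, 10,000-patient calibration checks —
match the scales at which the results are quoted; the whole suite runs in
a few seconds.

## Limitations

Fixed costs are treated as volume-independent within the year; per-capita
allocation is an accounting convention, not a causal claim. The
break-even and neutrality solvers inherit the linear model's assumption
that per-patient rates are mix-invariant (no case-mix interaction with
payer). The payer model is per-case and static — no discounting, no
horizon beyond the index hospitalization, and QoL scores rescale costs
rather than entering a QALY framework.
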