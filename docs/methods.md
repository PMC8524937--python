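# Methods

## Scope and modelling stance

`rtflow` models a radiotherapy department as two coupled, capacity-limited
stages with deterministic continuous (stock-and-flow) dynamics. The aim is
strategic comparison of capacity policies — which vacation layout builds the
smallest queue of prepared patients, needs the least overtime, wastes the
least linac time — not day-level production planning. Quantitative outputs
(queue sizes, overtime units) are meaningful relative to each other across
scenarios run on the same inflow and configuration; they are not forecasts.

All individual pre-treatment tasks (mould, CT/MRI/PET imaging, contouring,
treatment planning, patient QA) are merged into one preparation stage with a
single capacity and a fixed throughput time. Treatment technique
differences, patient-positioning requirements, machine assignment and linac
maintenance/downtime are out of scope; their effect is assumed equal across
compared scenarios.

## The flow model

Time advances in working days, `d = 5` per week; weekends carry neither
fractions nor preparation work. Stocks are real-valued per workflow group
(a diagnosis-by-intent class with representative fraction count `F_g`).

Each working day, in order:

1. **Arrivals.** On the first working day of each week, that week's
   referral counts join the awaiting-preparation stock.
2. **Preparation.** Entry is capacity-limited: `min(awaiting, c_prep/5)`
   patients start, drawn proportionally from each group's awaiting stock.
   Preparation is a conveyor (pipeline delay): everyone who enters exits
   exactly `L` working days later into the ready-to-start queue. Default
   `L = 8` (≈1.5 five-day weeks, the typical mould-to-QA span; results are
   insensitive within 5–10 days). The capacity limits *entries*; a reduced
   capacity therefore shows up in the ready queue only `L` days later.
3. **Treatment.** The in-treatment population is an aging chain indexed by
   remaining fractions. Ongoing courses are never paused: each consumes one
   fraction-unit per day unconditionally, and demand above the day's
   capacity is booked as overtime (the no-interruption norm: a treatment
   gap is clinically worse than staff overtime). Residual capacity admits
   new starts from the ready queue — FIFO by preparation-completion day,
   proportional across groups within a day — each consuming `w` units for
   the first fraction (default `w = 2`: extra time for patient information
   and technical verification at the first session). Leftover capacity is
   idle. Patients whose remaining count reaches zero complete.

Pooled tail groups carry a patient-weighted mean `F_g`, generally
fractional; starter mass is split between the two adjacent integer
remaining-fraction cohorts so that the expected fractions per patient equal
`F_g` exactly. A patient is counted in the in-treatment stock on every day
they receive a fraction, which makes the ample-capacity steady state obey
Little's law exactly: constant inflow `λ`/week at `F` fractions holds
`λF/5` patients in treatment.

Because every update is built from `min`, `+` and `×`:

* cumulative arrivals = awaiting + in-preparation + ready + in-treatment +
  completed, every day, to numerical precision;
* fractions given + fractions still owed = `Σ_g F_g · starts_g`, every day;
* `delivered = capacity − idle + overtime`, every day;
* scaling arrivals and both capacities by `k > 0` scales all trajectories
  by `k`;
* pointwise-larger treatment capacity never lengthens the ready queue.

The test suite asserts each of these, plus exact (≤1e−9) agreement with an
independently written per-patient event-list simulator on integer instances
where discrete and continuous semantics coincide.

## Vacation scenarios and metrics

A scenario reduces preparation capacity by `r_prep` and treatment capacity
by `r_treat` over equal-length windows of whole weeks; the preparation
window starts 0–4 weeks earlier. The packaged nine-scenario suite spans
8/6/4-week windows, 30/50/70 % reductions and offsets 0/1/2/4 weeks, placed
by default at treatment-vacation start week 27 of a 70-week horizon (a
January start puts week 27 at the end of June; the placement is
configurable).

Runs start from an empty system; the ~26 pre-vacation weeks serve as
warm-up. Scenario metrics (peak ready queue and its week, overtime and idle
totals) are therefore read over a configurable analysis window, by default
`[prep-window start − 4, treatment-window end + 4]` weeks. The default
excludes both the fill-up transient and late-horizon echo effects (the
delayed release of the awaiting-preparation backlog can produce a secondary
queue wave many weeks after the episode, which belongs to the next planning
period rather than to the compared vacation layouts); the full daily and
weekly series remain available on the result object. Window utilizations
(pre/during/post, defaults 4 weeks on each side) are delivered over
available fraction-units and exceed 1 under overtime.

## Baseline calibration

For scenario comparison, baseline capacities are set to the lowest level
that does not build a persistent queue. "Persistent" is operationalised on
a no-vacation run as: the terminal weekly level of the stage's queue
(awaiting-preparation for the preparation stage, ready-to-start for the
treatment stage) exceeds its mid-horizon level by more than a tolerance
(default 1 patient). `calibrate_baseline` bisects the capacity on a unit
grid (both the criterion and the grid are configurable) and verifies
minimality: one resolution step below the returned value fails the
criterion. On constant-inflow instances the result matches the closed-form
load, e.g. 10 patients/week at 4 fractions and `w = 2` needs
`10·(4+1)/5 = 10` units/day.

## Synthetic referral extracts

Real booking extracts are department-confidential, so the generator
emulates their statistical structure: weekly referral counts are
Poisson(`45.8`/week ≈ 3209 referrals per 70 weeks, a large-department
volume); each referral is curative with probability 0.65; diagnosis groups
are drawn from a Zipf-like law (`p_k ∝ k^−1.4`) over 128 raw
diagnosis-by-intent workflows split between the intents; fraction counts
are uniform integers, 15–35 for curative and 1–10 for palliative courses.
The tail exponent is calibrated so the 80/20 cut reproduces the ~20-group
aggregated case mix characteristic of such extracts (15–30 across seeds,
asserted over 10 seeds in the tests). Optional duplicate and non-logical
rows (zero fractions, unknown intent, missing referral week) can be
injected at stated rates and are recovered exactly by the cleaning stage.
Everything is reproducible from the seed.

What the generator does **not** emulate: seasonality of referrals (weekly
means are homogeneous; a sinusoidal modulation flag exists but is off by
default), true inter-arrival variance, diagnosis-specific fractionation
schedules, re-irradiation correlation (multiple courses arise only as
independent draws), and referral-to-booking delays. Passing scenario tests
therefore demonstrate the engine's comparative behaviour under a stationary
inflow, not a reproduction of any department's year. This matters for one
family of results: policies that move the preparation vacation much earlier
than the treatment vacation interact strongly with the inflow pattern. With
a stationary inflow, the awaiting-preparation backlog built during the
preparation vacation is released at full preparation capacity while
treatment is still reduced, producing a ready-queue surge; with a summer
referral dip (as real extracts show) the backlog, and with it the surge,
largely disappears — a unit test (`test_summer_referral_dip_restores_prep_first_advantage`)
demonstrates the contrast. Comparisons involving large preparation offsets
should accordingly be read against the department's actual seasonal
referral pattern.

## Numerical choices and degenerate inputs

* Stocks are float64; a guard raises on any stock below −1e−9 (unreachable
  by construction) and clips round-off negatives to zero.
* Pareto cut: groups sorted by count descending, ties broken
  lexicographically by `diagnosis|intent` label; the group that first
  reaches the cumulative share is included. `pareto_share = 1` disables
  pooling; empty input yields an empty case mix.
* Scaled weekly counts stay fractional — rounding would distort low-volume
  groups in a continuous model.
* Week indexing is ISO-based, 1-relative to the earliest referral's week.
* Cleaning is total: validity rules run before deduplication
  (first-occurrence kept on `patient_id`+`course_id`), and every removal is
  reported with its reason and row number.
* Zero treatment capacity yields no starts and unbounded ready growth; zero
  inflow yields an identically idle system — both covered by extreme-value
  tests.
* `run_suite` output is sorted by scenario id, so it is invariant to the
  order scenarios are supplied.

## Problem sizes used in the shipped checks

The packaged verification runs use 70-week horizons at the ~46-referrals/
week scale (≈3200 records, ~21 groups): conservation across 100 seeds,
scenario-ordering checks on metrics averaged over 5 seeds, oracle
equivalence on 60 instances of ≤5 groups and ≤20 weeks, and calibration on
60-week constant-inflow instances. A single 70-week suite evaluation (nine
scenarios) takes well under a second per scenario on one CPU.

## Known limitations

* One aggregate preparation capacity hides profession-level bottlenecks
  (physicists vs nurses vs oncologists) and sub-step interactions.
* The FIFO start discipline has no medical priority classes; urgent
  palliative patients would in reality overtake.
* Whole-week vacation windows and equal window lengths for both stages.
* The conveyor is a fixed pipeline delay; a first-order (exponential)
  delay would smear completions but leave throughput identical.
* Overtime is reported in fraction-units above capacity, not staff-hours.
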