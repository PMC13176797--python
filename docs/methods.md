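# Methods

`warfce` implements a lifetime Markov cohort (state-transition) model
comparing three ways of managing warfarin therapy in non-valvular atrial
fibrillation (NVAF): usual care by prescribing clinicians (UC), a
structured anticoagulation management service (AMS), and patient
self-management with home INR testing (PSM). A 70-year-old US cohort is
followed in 3-month cycles for 30 years (120 cycles, to age 100) from a
modified societal and a payer perspective, with costs in 2024 USD and
both costs and outcomes discounted at 3%/year.

## Model structure

Eight health states: `WELL` (anticoagulated NVAF, no prior neurological
event), six post-stroke states — ischemic stroke (IS) or intracranial
hemorrhage (ICH), each minor / major / disabled — and absorbing `DEAD`.
Clinical events are mutually exclusive within a cycle:

* From `WELL`: a first stroke (split into subtype by an assumed 0.85/0.15
  IS/ICH proportion, then into severity by the printed severity
  distributions; the fatal tier goes directly to `DEAD`), or a major
  extracranial hemorrhage (MEH, ISTH definition) — transient: the
  non-fatal 98.53% returns to `WELL` within the cycle carrying an acute
  cost and a 2-week disutility, the fatal 1.47% dies — or neither.
* From a post-stroke state: recurrence only, at a treatment-independent
  annual rate of 2.72%. Recurrent severity is drawn from the same
  subtype's severity distribution truncated to same-or-worse than the
  current tier and renormalized, with the subtype's fatal share retained
  (a configurable `stay-in-place` alternative keeps all non-fatal
  recurrences in the current state). Cross-subtype transitions and
  post-stroke MEH are structurally excluded.
* Background mortality applies to every alive state: the life-table
  annual probability is converted to a hazard, multiplied by the AF
  mortality multiplier (1.3), and converted to a per-cycle probability —
  multiplication on the hazard scale keeps probabilities valid for any
  multiplier.

Annual rates become cycle probabilities via the constant-hazard transform
`1 - exp(-r*t)`; strategy relative risks (stroke: 1 / 0.95 / 0.5; MEH:
1 / 0.89 / 0.98 for UC / AMS / PSM) act multiplicatively on the hazard
before conversion. Within `WELL`, stroke and MEH compete as independent
constant hazards: the combined event probability `1 - exp(-(r_s+r_m)t)`
is allocated proportionally to the two rates (the exact competing-risks
solution for constant hazards); background death is applied first and
event probabilities are conditioned on surviving it, which keeps every
transition row stochastic without ad-hoc renormalization. The ICH
severity proportions are printed summing to 0.98 and are renormalized to
1 at load time (raw values preserved, warning emitted).

Accrual convention: occupancy at the start of each cycle earns that
cycle's life years, QALYs and management/maintenance costs; there is no
half-cycle correction by default (a switch exists), matching
spreadsheet-style cohort models. Discounting uses
`(1 + r)^(-cycle/4)` — discrete annual compounding with fractional-cycle
exponents.

## Utilities

Baseline NVAF utility 0.81. Neurological events carry permanent
decrements (minor 0.29; major and disabled 0.45), applied by subtraction
and clamped at 0 with a warning if a sampled decrement exceeds the
baseline. A non-fatal MEH subtracts 0.181 for exactly 2 of the cycle's 13
weeks. Disutilities are stored as positive decrements; printed signs are
presentation only.

## Costs

Categories and conventions (all 2024 USD):

* **Drug**: warfarin 0.67/day × 91.25 days/cycle, every alive state.
* **Clinic visits and INR labs**: month-level schedules summed into
  cycles. UC: 3/month in months 1–2, then 1 per 2 months (6.5 visits in
  cycle 0, 1.5 thereafter). AMS: 2/week in weeks 1–2, every 2 weeks to
  month 2, 3 per 2 months in months 3–6, then 5 per 6 months (8.5 /
  4.5 / 2.5 visits in cycles 0 / 1 / 2+; month 3 is counted inside the
  months-3–6 window, the self-consistent reading of the published
  week/month windows). Every UC/AMS visit is billed the visit fee
  (36.68 / 11.52) plus the 8.91 laboratory INR test. PSM follows the AMS
  clinic pattern during its one training cycle, then tests weekly at
  home (strips replace the laboratory fee).
* **PSM equipment**: training 124.44 and lancing device 9.99 once at
  entry; the 595 meter amortized straight-line over its 5-year lifespan
  (29.75/cycle) and recurring while alive, so replacement after year 5 is
  covered; 13 strip+lancet pairs (5.60 + 0.11) per home-testing cycle.
* **Acute events**: per new event, by severity tier (IS and ICH:
  10,348 / 13,362 / 22,929; MEH 13,682), for first events and
  recurrences alike. Immediately fatal strokes carry no acute cost (no
  fatal tier is printed); fatal MEH carries the single printed MEH cost.
* **Maintenance**: quarterly by state of residence (IS 8,851 / 28,006 /
  51,838; ICH 17,448 / 81,255 / 27,239 — the ICH ordering is unusual but
  carried as printed).
* **Transport** (societal only): round trip per clinic visit,
  2 × 8.7 miles × 0.18/mile.
* **Caregiver** (societal only): informal-care hours by stroke severity
  (19 / 38 / 49 h/week) × 13 weeks × 23.80/hour, for post-stroke
  occupancy. The payer perspective excludes transport and caregiver
  costs; this exclusion is what produces the ≈30k societal–payer gap.

## Parameter uncertainty

Ranges are read as 95% intervals: sd = (high − low)/3.92, log scale for
log-normal rows (an explicit `sd` may be supplied instead, as for the
clinic distance whose dispersion is printed as an IQR). Gamma (event
rates, costs) and beta (utilities, discount rate) hyperparameters come
from moment matching — so sampled means reproduce the base values;
log-normal rows (relative risks, AF multiplier) use meanlog = ln(base),
reproducing the base as the median. An infeasible beta variance
(sd² ≥ m(1−m)) falls back to the widest beta with both shape parameters
≥ 1, with a warning. Rows printed without a distribution (severity
splits, visit schedules, the MEH disutility, the mileage rate, the
assumed subtype split) are fixed in the PSA; ranged fixed rows still
enter the one-way analysis.

PSA draws are independent across parameters and across the AMS/PSM
relative risks (no correlation structure is published), with one named
random substream per (seed, parameter, draw) so adding or removing a
parameter never perturbs the other draws. Draws yielding proportions or
utilities outside [0, 1] are re-drawn and counted, never clamped. The
one-way analysis reports the swing in the *absolute* net monetary
benefit of PSM at $100,000/QALY (societal); an incremental-vs-UC variant
is a flag. CEAC ties split equally among tied strategies.

## Synthetic data and verification oracles

The packaged life table `life_table_us_synthetic.csv` is a synthetic
Gompertz table (hazard 0.021/year at age 70, log-slope 0.095/year,
closed at age 100) approximating period US all-cause, all-sex mortality
around 2020; the national table the model conceptually requires is not
published with the inputs, so survival-dependent outputs are reproduced
at tolerance, not exactly. Under the AF multiplier 1.3 the event-free
cohort's undiscounted 30-year life expectancy is 13.6 years (discounted
10.7), inside the 8–14-year plausibility corridor used by the tests.

The generator (`warfce.synthetic`) produces seeded scenarios with
parameters drawn uniformly inside their printed ranges and Gompertz life
tables with jittered level — it emulates the *inputs* of the analysis,
not patient-level INR control, adherence or time-varying intervention
effects, so passing tests demonstrate arithmetic and structural
correctness, not real-world validity of the clinical assumptions. Two
independent oracles guard the engine: a geometric-series closed form for
the reduced alive/dead chain (agreement required to 1e-10) and a
multinomial micro-simulation that replays the engine's own per-cycle
probabilities (agreement within binomial noise at n = 200,000; it
deliberately shares the probability construction, which is itself tested
against closed forms, so it checks the trace arithmetic independently).

## Design choices where the ground truth is silent

* Stroke subtype split 0.85/0.15 (IS/ICH): the source for this value is
  cited upstream but no number is printed; 85% ischemic matches the
  usual anticoagulated-AF case mix, and the entry is first-class in the
  configuration and the tornado.
* The PSA varies all parameters simultaneously (standard practice), not
  one at a time.
* The AF mortality multiplier applies to all alive states, not only
  pre-event states.
* Recurrent strokes reuse the printed first-event severity
  distributions (truncated as described) — whether the original model
  did so is not stated.
* Visit-frequency translation, device amortization, round-trip
  transport, and the payer exclusion of caregiver time are as described
  above; each lives in the configuration or a documented switch so an
  alternative reading is one edit away.

## Known input inconsistencies and limitations

Two input rows are printed with a base value outside their own plausible
range and are carried verbatim, flagged `range_inconsistent` at load:
the annual stroke rate (base 1.15%, range 1.33–1.71%) and the MEH
disutility (base 0.181, range 0.106–0.114). The stroke-rate row matters:
the upstream trial that anchors the usual-care event rates reports a
warfarin-arm stroke incidence of ≈1.5%/year, consistent with the printed
*range* but not the printed base ("1.15" is plausibly a transposition of
"1.51"). With the verbatim base the model produces proportionally fewer
strokes — and therefore lower stroke-driven costs — than a
range-consistent rate would; the acceptance script reports both variants
(`rate_range_midpoint_` prefix) so the effect is visible, and the
one-way analysis flags the row (`base_outside`).

The model tracks no individual event histories (different event types
cannot co-occur), no DOAC switching, no myocardial infarction state, no
clinically relevant non-major bleeding, no productivity losses, and no
time-varying intervention effects. PSA quadrant shares inherit the very
wide published relative-risk intervals (the AMS stroke RR spans
0.10–8.94), which caps the probability that AMS beats UC near the
probability that a median-0.95 log-normal draw falls below 1 (≈52%);
narrower unpublished intervals would raise it.
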