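# warfce

Lifetime cost-effectiveness model of warfarin management strategies in
non-valvular atrial fibrillation (NVAF).

Warfarin requires regular INR monitoring, and how that monitoring is
organized changes both outcomes and costs. `warfce` implements a Markov
cohort model comparing three strategies for a 70-year-old US cohort on
warfarin for stroke prevention:

* **UC** — usual care by prescribing clinicians,
* **AMS** — a structured anticoagulation management service,
* **PSM** — patient self-management with weekly home INR testing.

The cohort moves quarterly between eight health states — healthy with
NVAF, six post-stroke states (ischemic stroke or intracranial
hemorrhage × minor/major/disabled severity), and death — for 30 years.
Annual event rates r become cycle probabilities via 1 − e^(−rΔt);
strategy relative risks act on the hazard; background mortality comes
from a life table with the AF hazard multiplied by 1.3. Each strategy
accrues discounted life years, QALYs (baseline utility 0.81, permanent
post-stroke decrements, transient bleed decrements) and 2024-USD costs
under payer and modified-societal perspectives, and strategies are
compared by incremental cost per QALY, dominance, and net monetary
benefit NMB = λ·QALY − cost at λ = $100,000/QALY. One-way (tornado) and
probabilistic sensitivity analysis with cost-effectiveness acceptability
curves quantify parameter uncertainty.

Intended for health-economics researchers and modelers who want a
scriptable, fully tested re-implementation of this decision problem with
every input in one editable YAML configuration.

## Worked example

```bash
python examples/base_case.py
```

prints (packaged inputs, synthetic US-like life table):

```
strategy  LY     QALY   societal $  payer $   strokes/10k
UC        10.51   8.24     110,744    82,246     1658
AMS       10.52   8.26     105,059    77,731     1583
PSM       10.58   8.43      62,985    48,330      868

Incremental analysis vs usual care (societal, $100,000/QALY threshold):
          incr_qalys  incr_cost      label         nmb
strategy
UC               NaN        NaN  reference  713036.120
AMS            0.020  -5684.766   dominant  720769.627
PSM            0.189 -47759.347   dominant  779681.673
```

Reading: discounted over a lifetime, self-management roughly halves
stroke events (868 vs 1658 per 10,000), which adds ≈0.19 QALYs and saves
≈$47,800 per patient versus usual care — PSM *dominates* (better and
cheaper), and the structured clinic dominates usual care more modestly.

Other examples: `examples/tornado.py` (which inputs move the result
most), `examples/psa_ceac.py` (probabilistic analysis and acceptability
curves), `examples/synthetic_oracle_check.py` (engine verified against a
closed form and a micro-simulation). The same analyses are available
from the shell: `warfce base|owsa|psa|ceac --out DIR` writes CSV/JSON
tables, plots and a provenance manifest.

Two input rows are printed inconsistently in the source tables (base
value outside its own plausible range) and are deliberately carried
verbatim and flagged at load time; see `docs/methods.md` for the full
model description, conventions, and the consequences of those flagged
rows.

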