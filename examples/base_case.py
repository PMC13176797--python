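"""Deterministic base case: lifetime outcomes of the three strategies.

Runs the packaged inputs (70-year-old US warfarin cohort with
non-valvular atrial fibrillation, quarterly cycles to age 100) and prints
discounted life years, QALYs and lifetime costs per patient under the
modified societal and payer perspectives, plus the incremental
comparison against usual care.  Self-management is expected to dominate:
fewer strokes mean more QALYs and lower long-term care costs.
"""

import warnings

import warfce

with warnings.catch_warnings():
    warnings.simplefilter("ignore", UserWarning)  # documented flagged rows
    params = warfce.load_parameters()
life_table = warfce.default_life_table()

results = warfce.base_case(params, life_table)

print("strategy  LY     QALY   societal $  payer $   strokes/10k")
for strategy, res in results.items():
    print(f"{strategy.value:<8}  {res.life_years:5.2f}  {res.qalys:5.2f}"
          f"  {res.cost_societal:10,.0f}  {res.cost_payer:8,.0f}"
          f"  {res.events_per_10000['stroke_total']:7.0f}")

print("\nIncremental analysis vs usual care "
      "(societal, $100,000/QALY threshold):")
table = warfce.incremental_table(results, warfce.Strategy.UC)
print(table[["incr_qalys", "incr_cost", "label", "nmb"]].round(3).to_string())
print("\nA 'dominant' label means more QALYs at lower cost than usual "
      "care; NMB = 100,000 x QALY - cost.")
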