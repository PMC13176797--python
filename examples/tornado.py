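"""One-way sensitivity analysis of the self-management strategy's value.

Each ranged input is set to its low and high limit (all else at base) and
the model re-run; the swing is the resulting change in the absolute net
monetary benefit of self-management at $100,000/QALY (societal
perspective).  Large swings mark the inputs whose uncertainty matters
most: the self-management stroke relative risk, the baseline utility, the
discount rate and the AF mortality multiplier are expected on top.
"""

import warnings

import warfce

with warnings.catch_warnings():
    warnings.simplefilter("ignore", UserWarning)
    params = warfce.load_parameters()
life_table = warfce.default_life_table()

table = warfce.tornado(params, life_table, wtp=100_000.0)
print("top 10 of", len(table), "ranged parameters by NMB swing (USD):")
cols = ["parameter", "low", "high", "nmb_at_low", "nmb_at_high", "swing"]
top = table.head(10)[cols].copy()
for c in ("nmb_at_low", "nmb_at_high", "swing"):
    top[c] = top[c].round(0)
print(top.round(3).to_string(index=False))
flagged = table[table["base_outside"]]
if len(flagged):
    print("\nrows whose base-case NMB falls outside the low/high interval "
          "(documented input inconsistencies):",
          ", ".join(flagged["parameter"]))
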