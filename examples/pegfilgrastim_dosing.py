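"""Pegfilgrastim timing and dose reduction for a high-risk population.

One pegylated injection per cycle: the day x dose table is evaluated by
full simulation and the smallest dose whose best outcome stays within a
margin of the full-dose (6 mg) optimum is reported — the model-based
case for dose reduction in lower-risk patients.
"""

from granulosim import make_reference_params, make_toy_regimen, optimize_peg

params = make_reference_params("high")   # high leukopenic-risk toxicity set
regimen = make_toy_regimen("chop14_like")

res = optimize_peg(
    params, regimen,
    days=range(1, 9), doses=[1500.0, 3000.0, 6000.0],
    objective="wbcaoc",
)

print(res.table.pivot(index="day", columns="dose", values="outcome").round(2))
print(f"optimal day at 6000 ug : d{res.best_day} (WBCAOC {res.best_value:.2f})")
print(f"recommended dose       : {res.recommended_dose:.0f} ug at d{res.recommended_day} "
      f"(WBCAOC {res.recommended_value:.2f})")
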