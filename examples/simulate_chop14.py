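"""Simulate a CHOP-14-like course with and without filgrastim support.

Builds the six-cycle toy regimen, runs the coupled granulopoiesis model
from its untreated steady state, and prints the three leukotoxicity
measures plus the per-cycle leukocyte nadirs.  Lower WBCAOC/DoL and a
higher MLC mean milder leukopenia.
"""

import numpy as np

from granulosim import (
    GcsfSchedule,
    compute_outcomes,
    make_reference_params,
    make_toy_regimen,
    simulate,
)

params = make_reference_params()
regimen = make_toy_regimen("chop14_like")

for label, schedule in [
    ("no G-CSF", None),
    ("filgrastim d4-13", GcsfSchedule.consecutive("filgrastim", 4, 10, 300.0)),
    ("filgrastim d6-12", GcsfSchedule.consecutive("filgrastim", 6, 7, 300.0)),
]:
    result = simulate(params, regimen, schedule)
    m = compute_outcomes(result)
    nadirs = []
    for c in range(regimen.n_cycles):
        mask = (result.t >= c * 14.0) & (result.t < (c + 1) * 14.0)
        nadirs.append(result.wbc[mask].min())
    print(f"{label:18s} WBCAOC {m.wbcaoc:6.2f}  DoL {m.dol:5.2f} d  "
          f"MLC {m.mlc:.2f} e3/uL  cycle nadirs "
          + " ".join(f"{n:.2f}" for n in nadirs))

# WBCAOC is the area between the WBC curve and 4.0 x10^3/µL where the
# curve is below it; DoL the cumulative time spent below; MLC the overall
# minimum.  G-CSF support raises the nadirs and shrinks all three.
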