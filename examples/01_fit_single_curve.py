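"""Fit one dose-response curve with the EC50 and IC50 models.

Builds an 8-point half-log dilution series for a cytostatic drug (the true
response plateaus at 60% inhibition), fits both models and prints the fitted
parameters and residual standard errors.  The flexible EC50 model tracks the
plateau; the IC50 model, forced through asymptotes 0 and 100, cannot.
"""

import numpy as np

from adjauc import (
    DoseResponseCurve,
    LogisticParams,
    fit_ec50_model,
    fit_ic50_model,
    predict_response,
    residual_standard_error,
)

rng = np.random.default_rng(0)
x = 8000.0 / 3.1623 ** np.arange(7, -1, -1)  # 2.53 .. 8000 nM
truth = LogisticParams(a_min=0.0, a_max=60.0, ec50=200.0, hill=1.0)
y = predict_response(truth, x) + rng.normal(0, 3.0, x.size)
curve = DoseResponseCurve("DEMO", "MEKI-LIKE", "CL1", x, y)

for fit in (fit_ec50_model(curve), fit_ic50_model(curve)):
    p = fit.params
    print(
        f"{fit.model_kind:>4} model: A_min={p.a_min:6.2f}  A_max={p.a_max:6.2f}  "
        f"EC50={p.ec50:8.1f} nM  Hill={p.hill:4.2f}  "
        f"complete={fit.complete}  RSE={residual_standard_error(fit, curve):.2f}"
    )

print(
    "\nThe EC50 model recovers the 60% plateau and a small RSE; the IC50"
    "\nmodel's larger RSE is the cost of forcing a plateaued curve through"
    "\n100%, and its EC50 estimate is biased several-fold upward."
)
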