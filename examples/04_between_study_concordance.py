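"""Between-study concordance: adjusted vs unadjusted AUC on simulated screens.

Two simulated studies measure the same ground-truth sensitivities under very
different dose designs (top concentrations 8 uM vs 66 uM).  The pooled
Pearson correlation between the studies is computed for the unadjusted AUC
and for the adjusted AUC over the drugs' shared dose windows, with bootstrap
confidence intervals and permutation p-values.
"""

import pandas as pd

from adjauc import (
    DoseDesign,
    SimConfig,
    concordance_report,
    harmonized_table,
    records_to_frame,
    simulate_multistudy,
    six_metric_table,
)
from adjauc.tables_io import iter_curves, validate_screen_table

cfg = SimConfig(
    n_drugs=5,
    n_cell_lines=25,
    designs=(
        DoseDesign("NARROW", 8, 8000.0, 3.1623),
        DoseDesign("WIDE", 16, 66000.0, 2.0),
    ),
    seed=11,
)
tables, _ = simulate_multistudy(cfg)
tables = [validate_screen_table(t) for t in tables]

frames = {}
for t in tables:
    study = str(t["study"].iloc[0])
    frames[study] = records_to_frame(
        six_metric_table(iter_curves(t), grid_step=8.0)
    )
adj = records_to_frame(harmonized_table(tables, grid_step=8.0).records)
for study in frames:
    frames[study] = pd.concat(
        [frames[study], adj[adj["study"] == study]], ignore_index=True
    )

results = concordance_report(
    frames, ("AUC_IC50", "ADJ_AUC_IC50"), n_resample=500, seed=1, per_drug=False
)
for r in results:
    print(
        f"{r.metric:13} r={r.pearson_r:.3f}  "
        f"95% CI [{r.ci_low:.3f}, {r.ci_high:.3f}]  p={r.p_value:.3g}  "
        f"n={r.n_pairs}"
    )

print(
    "\nAdjusting the AUC to the shared dose window raises the between-study"
    "\ncorrelation: the residual disagreement is assay noise, not dose design."
)
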