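"""Run the full screening funnel on the candidate library.

Gates: rule of five → activity threshold (all models ≥ 5.0 pEC50, i.e.
predicted EC50 ≤ 10 μM) → ranking by the externally supplied dock scores.
The dock scores and the SVM/BNT predicted-activity columns are published
inputs shipped with the package; the MLR prediction comes from the frozen
equation evaluated on descriptors computed here. The printed table mirrors a
ranked screening report: rank 1 is the best-docking survivor.
"""

from phytoscreen import (
    DS_EMULATION,
    eq1_model,
    fixture_library,
    frozen_table_model,
    run_screen,
    table1_inputs,
)
from phytoscreen.screen import ScreenConfig, report_dataframe

published = table1_inputs()
dock = dict(zip(published["name"], published["dock_score"]))
models = {
    "mlr": eq1_model(),
    "svr": frozen_table_model(dict(zip(published["name"], published["pEC50_svm"]))),
    "bayes": frozen_table_model(dict(zip(published["name"], published["pEC50_bnt"]))),
}
library = [g for g in fixture_library() if g.name in set(published["name"])]

records = run_screen(library, models, dock,
                     ScreenConfig(activity_threshold=5.0, conventions=DS_EMULATION))
report = report_dataframe(records)
cols = ["rank", "compound_id", "dock_score", "pEC50_mlr", "pEC50_svr", "pEC50_bayes"]
print(report[cols].to_string(index=False))
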