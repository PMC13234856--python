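"""Run the five-stage feature-selection cascade on a synthetic table.

ICC reproducibility filter -> z-score -> univariate test -> Spearman
redundancy pruning -> mRMR -> LASSO, all fit on the training rows only.
"""

import warnings

import numpy as np
import pandas as pd

from habitat_radiomics.selection import SelectionConfig, run_cascade

warnings.simplefilter("ignore")
rng = np.random.default_rng(0)

n, p = 80, 60
ids = [f"p{i}" for i in range(n)]
labels = pd.Series(rng.integers(0, 2, size=n), index=ids)
table = pd.DataFrame(rng.normal(size=(n, p)), index=ids,
                     columns=[f"noise{i}" for i in range(p)])
table["signal"] = labels + rng.normal(0, 0.3, n)          # outcome-linked
table["signal_twin"] = table["signal"] + rng.normal(0, 0.02, n)  # redundant
# second-rater table: everything reproducible except one unstable feature
rater2 = table + rng.normal(0, 0.05, size=table.shape)
rater2["noise0"] = rng.normal(size=n)

report = run_cascade(
    table, rater2, labels, train_ids=ids[:56],
    config=SelectionConfig(mrmr_k=15, lasso_folds=5), pool="demo",
)

for stage, survivors in report.stages.items():
    print(f"{stage:12s} {len(survivors):3d} features")
print(f"\nselected: {report.selected}")
# 'signal' survives every stage; its near-duplicate twin is removed at the
# Spearman step, the irreproducible feature at the ICC step, and the noise
# bulk at the univariate/LASSO steps.
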