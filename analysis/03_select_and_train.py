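"""Feature selection and classifier grid on the training cohort.

Stability-selects the three 5-feature bins (Wilcoxon rank-sum, MRMR,
random-forest importance; stratified 3-fold x 100 iterations) on D1, then
cross-validates the 4-learner x 3-bin grid and picks the best combination by
AUC — the NGAHIC.
"""

import sys
import warnings

import numpy as np
import pandas as pd

from ngahic.classify import pick_ngahic, train_eval_grid
from ngahic.selection import RANK_METHODS, stability_select

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
warnings.simplefilter("ignore")

X1 = pd.read_csv("results/data/features_d1.csv", index_col=0)
y1 = pd.read_csv("results/data/cohort_d1.csv", index_col=0).loc[X1.index, "recurrence"].to_numpy()

bins = [stability_select(X1, y1, m, n_iter=100, seed=SEED) for m in RANK_METHODS]
pd.DataFrame(
    [{"method": b.method, "rank": i + 1, "feature": f, "stability": b.stability_scores[f]}
     for b in bins for i, f in enumerate(b.features)]
).to_csv("results/feature_bins.csv", index=False)

for b in bins:
    print(f"{b.method} bin: " + ", ".join(
        f"{f} ({b.stability_scores[f]:.2f})" for f in b.features))

grid = train_eval_grid(X1, y1, bins, seed=SEED, n_repeats=10)
rows = pd.DataFrame([{
    "learner": r.learner, "bin": r.bin_method,
    "auc": f"{r.auc:.2f} ± {r.auc_sd:.2f}",
    "accuracy": f"{r.accuracy:.2f} ± {r.accuracy_sd:.2f}",
    "specificity": f"{r.specificity:.2f} ± {r.specificity_sd:.2f}",
    "sensitivity": f"{r.sensitivity:.2f} ± {r.sensitivity_sd:.2f}",
} for r in grid])
rows.to_csv("results/training_grid.csv", index=False)
print("\n12-combination training grid:\n" + rows.to_string(index=False))

best = pick_ngahic(grid)
print(f"\nNGAHIC = {best.learner} + {best.bin_method} bin "
      f"(training AUC {best.auc:.2f} ± {best.auc_sd:.2f})")
np.savetxt("results/ngahic_choice.txt", [f"{best.learner},{best.bin_method}"], fmt="%s")
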