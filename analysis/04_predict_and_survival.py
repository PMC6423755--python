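"""Held-out prediction and the downstream survival / IHC statistics.

Retrains the chosen NGAHIC combination on all of D1, calls recurrence on D2
at the strict 0.5 probability threshold, and runs the survival battery:
Kaplan-Meier curves by call, the log-rank test, univariate and multivariate
Cox models, and the HER2/Ki67 association tests.
"""

import sys
import warnings

import numpy as np
import pandas as pd

from ngahic.classify import auc_brute_force, confusion_metrics, predict_recurrence, train_final
from ngahic.selection import FeatureBin
from ngahic.simulate import generate_ihc_table
from ngahic.survival import (
    MULTIVARIATE_COMPACT,
    association_test,
    cox_fit,
    km_curve,
    logrank_by_group,
    univariate_cox,
)

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
warnings.simplefilter("ignore")

X1 = pd.read_csv("results/data/features_d1.csv", index_col=0)
d1 = pd.read_csv("results/data/cohort_d1.csv", index_col=0)
X2 = pd.read_csv("results/data/features_d2.csv", index_col=0)
d2 = pd.read_csv("results/data/cohort_d2.csv", index_col=0)
learner, bin_method = open("results/ngahic_choice.txt").read().strip().split(",")
bins = pd.read_csv("results/feature_bins.csv")
features = bins[bins["method"] == bin_method].sort_values("rank")["feature"].tolist()

model = train_final(X1, d1["recurrence"].to_numpy(),
                    FeatureBin(method=bin_method, features=features), learner, seed=SEED)
calls = predict_recurrence(model, X2)
probs = np.array([c.probability for c in calls])
d2["ngahic"] = [c.label for c in calls]
y2 = d2["recurrence"].to_numpy()

auc = auc_brute_force(y2, probs)
acc, spec, sens = confusion_metrics(y2, probs)
print(f"D2 held-out: AUC={auc:.2f} accuracy={acc:.2f} "
      f"specificity={spec:.2f} sensitivity={sens:.2f}")

for g, sub in d2.groupby("ngahic"):
    km_curve(sub["time_months"], sub["event"]).to_csv(f"results/km_ngahic_{g}.csv", index=False)
stat, p = logrank_by_group(d2, "ngahic")
print(f"log-rank NGAHIC+ vs NGAHIC-: chi2={stat:.2f}, p={p:.3g}")

uni = univariate_cox(d2)
multi = cox_fit(d2, ["ngahic", *MULTIVARIATE_COMPACT])
table = pd.DataFrame([
    {"model": m, "variable": s.variable, "HR": round(s.hazard_ratio, 2),
     "CI95": f"({s.ci95[0]:.2f}-{s.ci95[1]:.2f})", "p": f"{s.p_value:.3g}"}
    for m, summaries in (("univariate", uni), ("multivariate", multi)) for s in summaries
])
table.to_csv("results/survival_tables.csv", index=False)
print(table.to_string(index=False))

ihc = generate_ihc_table(d2, group_col="ngahic", seed=SEED)
ihc.to_csv("results/cohort_d2_ihc.csv")
for marker, method in (("her2_positive", "fisher"), ("ki67_positive", "chisq")):
    odds, p, tab = association_test(ihc["ngahic"], ihc[marker], method=method)
    pos_rate = 100 * ihc.loc[ihc["ngahic"] == 1, marker].mean()
    neg_rate = 100 * ihc.loc[ihc["ngahic"] == 0, marker].mean()
    print(f"{marker}: {pos_rate:.1f}% vs {neg_rate:.1f}% positive "
          f"(NGAHIC+ vs NGAHIC-), {method} p={p:.3g}")
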