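"""Intra-tumor heterogeneity check.

Emulates a second tumor punch per D2 patient (same group structure, fresh
noise), re-calls recurrence with the trained NGAHIC, and reports per-patient
call agreement plus the log-rank separation on the second-punch cohort.
"""

import sys
import warnings

import numpy as np
import pandas as pd

from ngahic.classify import predict_recurrence, train_final
from ngahic.pipeline import heterogeneity_check
from ngahic.selection import FeatureBin
from ngahic.simulate import CohortSimParams, features_for_labels

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

X3 = features_for_labels(d2["recurrence"], CohortSimParams(), seed=SEED + 7, index=d2.index)
X3.to_csv("results/data/features_d3.csv")


def frame(calls):
    return pd.DataFrame(
        {"probability": [c.probability for c in calls], "ngahic": [c.label for c in calls]},
        index=pd.Index([c.spot_id for c in calls], name="patient_id"),
    )


calls_d2 = frame(predict_recurrence(model, X2))
calls_d3 = frame(predict_recurrence(model, X3))
het = heterogeneity_check(calls_d2, calls_d3, d2)
pd.Series(het).to_csv("results/heterogeneity.csv")
print(f"D2 vs D3 call agreement: {het['agreement']:.2f}")
print(f"log-rank on D3 calls: chi2={het['logrank_statistic']:.2f}, p={het['logrank_p']:.3g}")
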