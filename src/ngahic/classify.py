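"""The 4-learner x 3-selector classifier grid and the NGAHIC recurrence call.

Learners: linear discriminant analysis (ALD), quadratic discriminant
analysis (AQD), linear support-vector machine with probability calibration
(MSV) and random forest (RF).  Crossing them with the three feature bins
gives 12 combination modes; the combination with the best cross-validated
AUC on the training cohort is the NGAHIC.  A spot is called
recurrence-positive when its predicted probability strictly exceeds the
0.5 threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.calibration import CalibratedClassifierCV
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .selection import FeatureBin

log = logging.getLogger(__name__)

RECURRENCE_THRESHOLD = 0.5
LEARNER_ORDER = ("ALD", "AQD", "MSV", "RF")
BIN_ORDER = ("WRST", "MRMR", "RF")


@dataclass
class ComboResult:
    """Cross-validated metrics of one learner x feature-bin combination."""

    learner: str
    bin_method: str
    auc: float
    auc_sd: float
    accuracy: float
    accuracy_sd: float
    specificity: float
    specificity_sd: float
    sensitivity: float
    sensitivity_sd: float

    def __post_init__(self) -> None:
        for m in (self.auc, self.accuracy, self.specificity, self.sensitivity):
            if not 0.0 <= m <= 1.0:
                raise ValueError("metrics must be in [0, 1]")


@dataclass
class RecurrenceCall:
    spot_id: str
    probability: float
    label: int  # positive iff probability > threshold (strict)


class RegularizedQDA(BaseEstimator, ClassifierMixin):
    """Gaussian quadratic discriminant with shrinkage-regularized class
    covariances.

    Each class covariance is shrunk toward a scaled identity,
    ``(1 - reg) * S_k + reg * tr(S_k)/p * I``, so the fit stays defined when
    a class has fewer samples than features (the usual situation with
    5-feature bins and small training cohorts).  A singular raw covariance
    is regularized rather than rejected, with a log entry.
    """

    def __init__(self, reg: float = 0.2):
        self.reg = reg

    def fit(self, X, y):
        X = np.asarray(X, float)
        y = np.asarray(y).astype(int)
        self.classes_ = np.unique(y)
        p = X.shape[1]
        self.means_, self.precisions_, self.logdets_, self.priors_ = [], [], [], []
        for c in self.classes_:
            sub = X[y == c]
            mean = sub.mean(axis=0)
            centered = sub - mean
            S = centered.T @ centered / max(len(sub) - 1, 1)
            if np.linalg.matrix_rank(S) < p:
                log.info("singular covariance for class %s: applying shrinkage", c)
            scale = max(np.trace(S) / p, 1e-12)
            S = (1.0 - self.reg) * S + self.reg * scale * np.eye(p)
            self.means_.append(mean)
            self.precisions_.append(np.linalg.inv(S))
            self.logdets_.append(float(np.linalg.slogdet(S)[1]))
            self.priors_.append(len(sub) / len(X))
        return self

    def _log_posteriors(self, X):
        X = np.asarray(X, float)
        scores = np.empty((len(X), len(self.classes_)))
        for k in range(len(self.classes_)):
            d = X - self.means_[k]
            maha = np.einsum("ij,jk,ik->i", d, self.precisions_[k], d)
            scores[:, k] = -0.5 * (maha + self.logdets_[k]) + np.log(self.priors_[k])
        return scores

    def predict_proba(self, X):
        s = self._log_posteriors(X)
        s -= s.max(axis=1, keepdims=True)
        e = np.exp(s)
        return e / e.sum(axis=1, keepdims=True)

    def predict(self, X):
        return self.classes_[np.argmax(self._log_posteriors(X), axis=1)]


def make_learner(name: str, seed: int = 0):
    """Instantiate one of the four learners.

    Discriminants and the SVM operate on z-scored features (training-fold
    statistics); the forest uses raw values.  Discriminant covariances are
    regularized so singular within-class covariance degrades gracefully.
    """
    if name == "ALD":
        clf = LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto")
    elif name == "AQD":
        clf = RegularizedQDA()
    elif name == "MSV":
        # linear SVM with a held-out-fold sigmoid (Platt) probability fit
        clf = CalibratedClassifierCV(
            SVC(kernel="linear", C=1.0, random_state=seed), method="sigmoid", cv=3, ensemble=False
        )
    elif name == "RF":
        return RandomForestClassifier(n_estimators=100, random_state=seed)
    else:
        raise ValueError(f"unknown learner {name!r}")
    return Pipeline([("scale", StandardScaler()), ("clf", clf)])


def confusion_metrics(y_true: np.ndarray, y_prob: np.ndarray, threshold: float = RECURRENCE_THRESHOLD):
    """(accuracy, specificity, sensitivity) at the strict > threshold call."""
    y_true = np.asarray(y_true).astype(int)
    y_pred = (np.asarray(y_prob) > threshold).astype(int)
    tp = int(((y_pred == 1) & (y_true == 1)).sum())
    tn = int(((y_pred == 0) & (y_true == 0)).sum())
    fp = int(((y_pred == 1) & (y_true == 0)).sum())
    fn = int(((y_pred == 0) & (y_true == 1)).sum())
    accuracy = (tp + tn) / max(len(y_true), 1)
    specificity = tn / (tn + fp) if tn + fp else 0.0
    sensitivity = tp / (tp + fn) if tp + fn else 0.0
    return accuracy, specificity, sensitivity


def _cv_metrics(X: np.ndarray, y: np.ndarray, learner_name: str, n_folds: int, seed: int):
    """Per-fold AUC/accuracy/specificity/sensitivity."""
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    rows = []
    for fold, (tr, te) in enumerate(skf.split(X, y)):
        model = make_learner(learner_name, seed=seed + fold)
        model.fit(X[tr], y[tr])
        prob = model.predict_proba(X[te])[:, 1]
        if len(np.unique(y[te])) == 2:
            auc = roc_auc_score(y[te], prob)
        else:  # degenerate fold; stratification should prevent this
            auc = np.nan
        acc, spec, sens = confusion_metrics(y[te], prob)
        rows.append((auc, acc, spec, sens))
    return np.array(rows, dtype=float)


def train_eval_grid(
    X: pd.DataFrame,
    y: np.ndarray,
    bins: list[FeatureBin],
    seed: int = 0,
    n_folds: int = 3,
    n_repeats: int = 10,
) -> list[ComboResult]:
    """Cross-validated evaluation of every learner x bin combination on the
    training cohort; exactly 12 results (4 learners x 3 bins)."""
    if len(bins) != 3:
        raise ValueError("expected exactly 3 feature bins")
    y = np.asarray(y).astype(int)
    results = []
    rng = np.random.default_rng(seed)
    for learner in LEARNER_ORDER:
        for fb in sorted(bins, key=lambda b: BIN_ORDER.index(b.method)):
            sub = X[fb.features].to_numpy(float)
            folds = np.vstack(
                [
                    _cv_metrics(sub, y, learner, n_folds, int(rng.integers(2**31)))
                    for _ in range(n_repeats)
                ]
            )
            mean = np.nanmean(folds, axis=0)
            sd = np.nanstd(folds, axis=0, ddof=1)
            results.append(
                ComboResult(
                    learner=learner,
                    bin_method=fb.method,
                    auc=float(mean[0]),
                    auc_sd=float(sd[0]),
                    accuracy=float(mean[1]),
                    accuracy_sd=float(sd[1]),
                    specificity=float(mean[2]),
                    specificity_sd=float(sd[2]),
                    sensitivity=float(mean[3]),
                    sensitivity_sd=float(sd[3]),
                )
            )
    return results


def pick_ngahic(results: list[ComboResult]) -> ComboResult:
    """The best combination by mean AUC; ties broken by accuracy, then
    specificity, then sensitivity, then the fixed learner/bin order."""
    if len(results) != 12:
        raise ValueError(f"expected 12 results, got {len(results)}")

    def key(r: ComboResult):
        return (
            -r.auc,
            -r.accuracy,
            -r.specificity,
            -r.sensitivity,
            LEARNER_ORDER.index(r.learner),
            BIN_ORDER.index(r.bin_method),
        )

    return min(results, key=key)


@dataclass
class TrainedModel:
    """A fitted learner pinned to its feature bin."""

    learner: str
    bin_method: str
    features: list[str]
    estimator: object

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        missing = [f for f in self.features if f not in X.columns]
        if missing:
            raise ValueError(f"missing feature columns: {missing}")
        return self.estimator.predict_proba(X[self.features].to_numpy(float))[:, 1]


def train_final(
    X: pd.DataFrame, y: np.ndarray, feature_bin: FeatureBin, learner: str, seed: int = 0
) -> TrainedModel:
    """Fit the chosen learner on the full training cohort restricted to its
    feature bin."""
    model = make_learner(learner, seed=seed)
    model.fit(X[feature_bin.features].to_numpy(float), np.asarray(y).astype(int))
    return TrainedModel(
        learner=learner,
        bin_method=feature_bin.method,
        features=list(feature_bin.features),
        estimator=model,
    )


def predict_recurrence(
    model: TrainedModel,
    X: pd.DataFrame,
    threshold: float = RECURRENCE_THRESHOLD,
) -> list[RecurrenceCall]:
    """Per-spot probability and the strict > threshold recurrence label."""
    if len(X) == 0:
        return []
    probs = model.predict_proba(X)
    return [
        RecurrenceCall(spot_id=str(idx), probability=float(p), label=int(p > threshold))
        for idx, p in zip(X.index, probs)
    ]


def auc_brute_force(y_true: np.ndarray, scores: np.ndarray) -> float:
    """Pairwise-concordance AUC (ties counted 1/2); independent oracle for
    small sets."""
    y_true = np.asarray(y_true).astype(int)
    scores = np.asarray(scores, float)
    pos = scores[y_true == 1]
    neg = scores[y_true == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes required")
    wins = 0.0
    for p in pos:
        for q in neg:
            wins += 1.0 if p > q else (0.5 if p == q else 0.0)
    return wins / (len(pos) * len(neg))
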