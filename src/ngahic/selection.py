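"""Feature ranking and stability selection.

Three ranking schemes — Wilcoxon rank-sum test (WRST), minimum-redundancy
maximum-relevance mutual information (MRMR) and random-forest impurity
importance (RF) — each wrapped in a randomized stratified 3-fold x
100-iteration stability-selection protocol.  The final bin of a scheme is
the k = 5 features most frequently appearing in the per-fold top-k lists.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold

log = logging.getLogger(__name__)

BIN_SIZE = 5
N_FOLDS = 3
N_ITER = 100
MRMR_BINS = 4

RANK_METHODS = ("WRST", "MRMR", "RF")


@dataclass
class FeatureBin:
    """Top-k features of one selection scheme with their stability scores."""

    method: str
    features: list[str]
    stability_scores: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.method not in RANK_METHODS:
            raise ValueError(f"unknown selection method {self.method!r}")
        if len(set(self.features)) != len(self.features):
            raise ValueError("feature bin contains duplicates")


def _check_two_classes(y: np.ndarray) -> None:
    if len(np.unique(y)) != 2:
        raise ValueError("both classes must be present")


def rank_wrst(X: pd.DataFrame, y: np.ndarray) -> tuple[list[str], pd.Series]:
    """Rank features by two-sided Wilcoxon rank-sum p-value (midrank ties;
    exact null when sample sizes permit).  Constant features get p = 1 by
    convention.  Ties in p are broken by feature name."""
    y = np.asarray(y)
    _check_two_classes(y)
    pos = X[y == 1].to_numpy(float)
    neg = X[y == 0].to_numpy(float)
    exact_regime = max(len(pos), len(neg)) <= 8
    if exact_regime:  # scipy picks the exact null when sizes permit and no ties
        p_arr = np.array(
            [
                stats.mannwhitneyu(pos[:, i], neg[:, i], alternative="two-sided").pvalue
                for i in range(X.shape[1])
            ]
        )
    else:
        p_arr = stats.mannwhitneyu(pos, neg, alternative="two-sided", method="asymptotic", axis=0).pvalue
    constant = np.all(np.vstack([pos, neg]) == np.vstack([pos, neg])[0], axis=0)
    if constant.any():
        for name in X.columns[constant]:
            log.info("constant feature %s: p = 1 by convention", name)
        p_arr = np.where(constant, 1.0, p_arr)
    p_arr = np.nan_to_num(p_arr, nan=1.0)
    series = pd.Series(p_arr, index=X.columns)
    order = sorted(series.index, key=lambda n: (series[n], n))
    return order, series.loc[order]


def _quantile_bin(X: np.ndarray, n_bins: int) -> np.ndarray:
    """Discretize each column into quantile bins (duplicate edges merged)."""
    out = np.zeros(X.shape, dtype=np.int64)
    qs = np.linspace(0, 1, n_bins + 1)[1:-1]
    for j in range(X.shape[1]):
        edges = np.unique(np.quantile(X[:, j], qs))
        out[:, j] = np.searchsorted(edges, X[:, j], side="right")
    return out


def mutual_information_bits(a: np.ndarray, b: np.ndarray) -> float:
    """I(a; b) in bits from two integer-coded vectors."""
    na, nb = int(a.max()) + 1, int(b.max()) + 1
    joint = np.bincount(a * nb + b, minlength=na * nb).astype(float).reshape(na, nb)
    joint /= joint.sum()
    pa = joint.sum(axis=1, keepdims=True)
    pb = joint.sum(axis=0, keepdims=True)
    nz = joint > 0
    return float((joint[nz] * np.log2(joint[nz] / (pa @ pb)[nz])).sum())


def rank_mrmr(
    X: pd.DataFrame, y: np.ndarray, n_bins: int = MRMR_BINS, top_k: int | None = None
) -> list[str]:
    """Greedy MRMR ranking: maximize I(f; label) minus the mean mutual
    information with already-selected features, on quantile-binned data."""
    y = np.asarray(y).astype(np.int64)
    _check_two_classes(y)
    if X.shape[1] < 2:
        raise ValueError("need >= 2 features for MRMR")
    names = list(X.columns)
    binned = _quantile_bin(X.to_numpy(float), n_bins)
    n_feat = len(names)
    limit = n_feat if top_k is None else min(top_k, n_feat)

    relevance = np.array([mutual_information_bits(binned[:, j], y) for j in range(n_feat)])
    selected: list[int] = []
    remaining = list(range(n_feat))
    redundancy_sum = np.zeros(n_feat)
    while len(selected) < limit:
        if selected:
            scores = relevance[remaining] - redundancy_sum[remaining] / len(selected)
        else:
            scores = relevance[remaining]
        # deterministic tie-break by feature name
        best_pos = min(range(len(remaining)), key=lambda p: (-scores[p], names[remaining[p]]))
        j = remaining.pop(best_pos)
        selected.append(j)
        if remaining and len(selected) < limit:
            for r in remaining:
                redundancy_sum[r] += mutual_information_bits(binned[:, r], binned[:, j])
    return [names[j] for j in selected]


def rank_rf_importance(
    X: pd.DataFrame, y: np.ndarray, n_trees: int = 100, seed: int = 0
) -> list[str]:
    """Rank by mean impurity-decrease importance of a seeded random forest."""
    y = np.asarray(y)
    _check_two_classes(y)
    if min(np.bincount(y.astype(int))) < 2:
        raise ValueError("need >= 2 spots per class")
    forest = RandomForestClassifier(n_estimators=n_trees, random_state=seed)
    forest.fit(X.to_numpy(float), y)
    imp = pd.Series(forest.feature_importances_, index=X.columns)
    return sorted(imp.index, key=lambda n: (-imp[n], n))


def _rank(method: str, X: pd.DataFrame, y: np.ndarray, k: int, seed: int, rf_trees: int) -> list[str]:
    if method == "WRST":
        return rank_wrst(X, y)[0][:k]
    if method == "MRMR":
        return rank_mrmr(X, y, top_k=k)
    if method == "RF":
        return rank_rf_importance(X, y, n_trees=rf_trees, seed=seed)[:k]
    raise ValueError(f"unknown selection method {method!r}")


def stability_select(
    X: pd.DataFrame,
    y: np.ndarray,
    method: str,
    k: int = BIN_SIZE,
    n_folds: int = N_FOLDS,
    n_iter: int = N_ITER,
    seed: int = 0,
    rf_trees: int = 50,
) -> FeatureBin:
    """Stability selection: rank within each training fold of a randomized
    stratified ``n_folds``-fold scheme repeated ``n_iter`` times; the bin is
    the ``k`` features with the highest selection frequency across all
    ``n_folds * n_iter`` fold-level top-k lists."""
    y = np.asarray(y).astype(int)
    _check_two_classes(y)
    if len(y) < n_folds * 2 or min(np.bincount(y)) < n_folds:
        raise ValueError("too few spots per class for stratified folding")
    rng = np.random.default_rng(seed)
    counts: dict[str, int] = {name: 0 for name in X.columns}
    rank_sum: dict[str, float] = {name: 0.0 for name in X.columns}
    n_lists = 0
    for _ in range(n_iter):
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=int(rng.integers(2**31)))
        for train_idx, _test in skf.split(X, y):
            top = _rank(method, X.iloc[train_idx], y[train_idx], k, int(rng.integers(2**31)), rf_trees)
            n_lists += 1
            for pos, name in enumerate(top[:k]):
                counts[name] += 1
                rank_sum[name] += pos
    freq = {n: counts[n] / n_lists for n in X.columns}
    # highest frequency; ties by better (lower) mean rank, then name
    def sort_key(n: str):
        mean_rank = rank_sum[n] / counts[n] if counts[n] else float("inf")
        return (-freq[n], mean_rank, n)

    chosen = sorted(X.columns, key=sort_key)[:k]
    return FeatureBin(method=method, features=chosen, stability_scores={n: freq[n] for n in chosen})
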