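"""End-to-end orchestration of the D1-train -> D2-test -> D3-heterogeneity
design, with a run directory, manifest and deterministic seeding."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classify import (
    ComboResult,
    auc_brute_force,
    confusion_metrics,
    pick_ngahic,
    predict_recurrence,
    train_eval_grid,
    train_final,
)
from .features import extract_spot_features, feature_names
from .selection import RANK_METHODS, stability_select
from .simulate import (
    CohortSimParams,
    SpotSimParams,
    features_for_labels,
    generate_cohort,
    generate_ihc_table,
    generate_spot_image,
)
from .survival import (
    MULTIVARIATE_COMPACT,
    association_test,
    cox_fit,
    km_curve,
    logrank_by_group,
    univariate_cox,
)

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All stage parameters of one pipeline run.

    ``feature_source`` selects how per-spot features arise: ``"images"``
    renders every patient's TMA spot and runs the full extraction;
    ``"matrix"`` uses the generator's feature matrix directly (the same
    statistical structure at a fraction of the cost).
    """

    out_dir: str = "results/run"
    seed: int = 0
    n_train: int = 60
    n_test: int = 100
    recurrence_fraction: float = 0.225
    hazard_ratio: float = 17.24
    effect_size: float = 1.5
    censor_rate: float = 0.1
    follow_up_cap: float = 60.0
    feature_source: str = "matrix"  # "matrix" | "images"
    spot_canvas: int = 256
    spot_n_nuclei: int = 60
    bin_size: int = 5
    n_folds: int = 3
    n_iter: int = 25
    grid_repeats: int = 10
    threshold: float = 0.5
    endpoint: str = "os"  # overall survival; "dss" restricts events to recurrence deaths

    def validate(self) -> None:
        if not 0 < self.threshold < 1:
            raise ValueError("threshold must be in (0, 1)")
        if self.feature_source not in ("matrix", "images"):
            raise ValueError("feature_source must be 'matrix' or 'images'")
        if self.endpoint not in ("os", "dss"):
            raise ValueError("endpoint must be 'os' or 'dss'")
        if self.n_train < 6 or self.n_test < 6:
            raise ValueError("cohort sizes must be >= 6")
        if self.n_folds < 2 or self.n_iter < 1 or self.grid_repeats < 1:
            raise ValueError("invalid cross-validation parameters")
        if self.bin_size < 1:
            raise ValueError("bin_size must be >= 1")
        if not 0 < self.recurrence_fraction < 1:
            raise ValueError("recurrence_fraction must be in (0, 1)")
        if self.hazard_ratio <= 0:
            raise ValueError("hazard_ratio must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def _config_hash(config: RunConfig) -> str:
    payload = json.dumps(asdict(config), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def _image_features(spot_params, ids, base: SpotSimParams) -> pd.DataFrame:
    rows = []
    for pid, sp in zip(ids, spot_params):
        sp = replace(sp, canvas=base.canvas, n_nuclei=base.n_nuclei)
        img, mask, _ = generate_spot_image(sp)
        fv = extract_spot_features(img, spot_id=pid)
        rows.append(fv.values.rename(pid))
    return pd.DataFrame(rows)


def _simulate_features(cohort_params: CohortSimParams, base: SpotSimParams, source: str):
    cohort, feats, spot_params = generate_cohort(cohort_params, base_spot=base)
    if source == "images":
        feats = _image_features(spot_params, cohort.index, base)
    return cohort, feats, spot_params


def run_pipeline(config: RunConfig) -> dict:
    """Execute simulate -> features -> select -> train -> evaluate ->
    survival -> heterogeneity and write all stage outputs plus a manifest.

    Identical configs produce identical outputs.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    master = np.random.default_rng(config.seed)
    seeds = {k: int(master.integers(2**31)) for k in ("d1", "d2", "d3", "select", "grid", "ihc")}

    base_spot = SpotSimParams(canvas=config.spot_canvas, n_nuclei=config.spot_n_nuclei)

    def cohort_params(n, seed):
        return CohortSimParams(
            n_patients=n,
            recurrence_fraction=config.recurrence_fraction,
            hazard_ratio=config.hazard_ratio,
            effect_size=config.effect_size,
            censor_rate=config.censor_rate,
            follow_up_cap=config.follow_up_cap,
            seed=seed,
        )

    try:
        d1_params = cohort_params(config.n_train, seeds["d1"])
        d1, X1, _ = _simulate_features(d1_params, base_spot, config.feature_source)
        d2_params = cohort_params(config.n_test, seeds["d2"])
        d2, X2, d2_spots = _simulate_features(d2_params, base_spot, config.feature_source)
    except Exception as exc:
        raise RuntimeError(f"stage 'simulate' failed: {exc}") from exc

    d1.to_csv(out / "cohort_d1.csv")
    d2.to_csv(out / "cohort_d2.csv")
    X1.to_csv(out / "features_d1.csv")
    X2.to_csv(out / "features_d2.csv")

    y1 = d1["recurrence"].to_numpy()
    try:
        bins = [
            stability_select(
                X1, y1, method, k=config.bin_size, n_folds=config.n_folds,
                n_iter=config.n_iter, seed=seeds["select"],
            )
            for method in RANK_METHODS
        ]
    except Exception as exc:
        raise RuntimeError(f"stage 'select' failed: {exc}") from exc
    pd.DataFrame(
        [
            {"method": b.method, "rank": i + 1, "feature": f, "stability": b.stability_scores[f]}
            for b in bins
            for i, f in enumerate(b.features)
        ]
    ).to_csv(out / "feature_bins.csv", index=False)

    try:
        grid = train_eval_grid(
            X1, y1, bins, seed=seeds["grid"], n_folds=config.n_folds, n_repeats=config.grid_repeats
        )
        best = pick_ngahic(grid)
        chosen_bin = next(b for b in bins if b.method == best.bin_method)
        model = train_final(X1, y1, chosen_bin, best.learner, seed=seeds["grid"])
    except Exception as exc:
        raise RuntimeError(f"stage 'train' failed: {exc}") from exc
    grid_df = pd.DataFrame([asdict(r) for r in grid])
    grid_df.to_csv(out / "training_grid.csv", index=False)

    try:
        calls = predict_recurrence(model, X2, threshold=config.threshold)
        probs = np.array([c.probability for c in calls])
        labels = np.array([c.label for c in calls])
        y2 = d2["recurrence"].to_numpy()
        test_auc = auc_brute_force(y2, probs) if len(np.unique(y2)) == 2 else float("nan")
        test_acc, test_spec, test_sens = confusion_metrics(y2, probs, config.threshold)
    except Exception as exc:
        raise RuntimeError(f"stage 'evaluate' failed: {exc}") from exc
    calls_df = pd.DataFrame(
        {"patient_id": [c.spot_id for c in calls], "probability": probs, "ngahic": labels}
    ).set_index("patient_id")
    calls_df.to_csv(out / "calls_d2.csv")

    d2s = d2.join(calls_df["ngahic"])
    if config.endpoint == "dss":
        d2s = d2s.assign(event=(d2s["event"] & d2s["recurrence"]).astype(int))
    try:
        km_groups = {
            int(g): km_curve(sub["time_months"], sub["event"])
            for g, sub in d2s.groupby("ngahic")
        }
        for g, curve in km_groups.items():
            curve.to_csv(out / f"km_ngahic_{g}.csv", index=False)
        if d2s["ngahic"].nunique() == 2:
            lr_stat, lr_p = logrank_by_group(d2s, "ngahic")
        else:
            lr_stat, lr_p = float("nan"), float("nan")
        uni = univariate_cox(d2s)
        multi = []
        if d2s["ngahic"].nunique() == 2:
            try:
                multi = cox_fit(d2s, ["ngahic", *MULTIVARIATE_COMPACT])
            except RuntimeError as exc:  # monotone likelihood is a statistical outcome
                log.warning("multivariate Cox diverged on this cohort: %s", exc)
    except Exception as exc:
        raise RuntimeError(f"stage 'survival' failed: {exc}") from exc
    pd.DataFrame([asdict(s) for s in uni]).to_csv(out / "survival_univariate.csv", index=False)
    pd.DataFrame([asdict(s) for s in multi]).to_csv(out / "survival_multivariate.csv", index=False)

    ihc = generate_ihc_table(d2s, group_col="ngahic", seed=seeds["ihc"]) if d2s["ngahic"].nunique() == 2 else None
    if ihc is not None:
        ihc.to_csv(out / "cohort_d2_ihc.csv")
        her2 = association_test(ihc["ngahic"], ihc["her2_positive"], method="fisher")
        ki67 = association_test(ihc["ngahic"], ihc["ki67_positive"], method="chisq")
    else:
        her2 = ki67 = (float("nan"), float("nan"), None)

    # D3: second punch from the same patients, new noise
    try:
        if config.feature_source == "images":
            d3_spots = [replace(sp, seed=(sp.seed + 1) % 2**31) for sp in d2_spots]
            X3 = _image_features(d3_spots, d2.index, base_spot)
        else:
            X3 = features_for_labels(d2["recurrence"], d2_params, seeds["d3"], index=d2.index)
        X3.to_csv(out / "features_d3.csv")
        calls3 = predict_recurrence(model, X3, threshold=config.threshold)
        het = heterogeneity_check(calls_df, _calls_frame(calls3), d2)
    except Exception as exc:
        raise RuntimeError(f"stage 'heterogeneity' failed: {exc}") from exc

    results = {
        "config_hash": _config_hash(config),
        "seeds": seeds,
        "version": __version__,
        "n_features": len(feature_names()),
        "bins": {b.method: b.features for b in bins},
        "grid": grid_df.to_dict(orient="records"),
        "ngahic": {"learner": best.learner, "bin": best.bin_method, "train_auc": best.auc},
        "test": {
            "auc": float(test_auc),
            "accuracy": float(test_acc),
            "specificity": float(test_spec),
            "sensitivity": float(test_sens),
        },
        "logrank_d2": {"statistic": float(lr_stat), "p": float(lr_p)},
        "cox_multivariate": [asdict(s) for s in multi],
        "her2": {"odds_ratio": her2[0], "p": her2[1]},
        "ki67": {"odds_ratio": ki67[0], "p": ki67[1]},
        "heterogeneity": het,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump({"config": asdict(config), **results}, fh, indent=2, default=str)
    return results


def train_test_experiment(
    seed: int,
    n_train: int = 60,
    n_test: int = 100,
    effect_size: float = 1.5,
    n_iter: int = 25,
    grid_repeats: int = 5,
    recurrence_fraction: float = 0.225,
) -> dict:
    """One D1-train / D2-test replicate without file output: stability-select
    the three bins, evaluate the 12-combo grid, pick the NGAHIC, and score it
    on the held-out cohort.  Returns the held-out metrics and the choice."""
    rng = np.random.default_rng(seed)
    s1, s2, s3, s4 = (int(rng.integers(2**31)) for _ in range(4))
    d1, X1, _ = generate_cohort(
        CohortSimParams(n_patients=n_train, effect_size=effect_size,
                        recurrence_fraction=recurrence_fraction, seed=s1)
    )
    d2, X2, _ = generate_cohort(
        CohortSimParams(n_patients=n_test, effect_size=effect_size,
                        recurrence_fraction=recurrence_fraction, seed=s2)
    )
    y1 = d1["recurrence"].to_numpy()
    y2 = d2["recurrence"].to_numpy()
    bins = [stability_select(X1, y1, m, n_iter=n_iter, seed=s3) for m in RANK_METHODS]
    grid = train_eval_grid(X1, y1, bins, seed=s4, n_repeats=grid_repeats)
    best = pick_ngahic(grid)
    model = train_final(y=y1, X=X1, feature_bin=next(b for b in bins if b.method == best.bin_method),
                        learner=best.learner, seed=s4)
    probs = model.predict_proba(X2)
    auc = auc_brute_force(y2, probs) if len(np.unique(y2)) == 2 else float("nan")
    acc, spec, sens = confusion_metrics(y2, probs)
    return {
        "learner": best.learner,
        "bin": best.bin_method,
        "train_auc": best.auc,
        "test_auc": float(auc),
        "test_accuracy": float(acc),
        "test_specificity": float(spec),
        "test_sensitivity": float(sens),
    }


def _calls_frame(calls) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "patient_id": [c.spot_id for c in calls],
            "probability": [c.probability for c in calls],
            "ngahic": [c.label for c in calls],
        }
    ).set_index("patient_id")


def heterogeneity_check(
    calls_a: pd.DataFrame, calls_b: pd.DataFrame, cohort_b: pd.DataFrame
) -> dict:
    """Per-patient agreement between calls on two punches of the same tumor,
    plus the log-rank test of the second punch's calls on cohort B."""
    missing = sorted(set(calls_a.index).symmetric_difference(calls_b.index))
    if missing:
        raise ValueError(f"unmatched patient ids: {missing}")
    agree = float((calls_a["ngahic"] == calls_b.loc[calls_a.index, "ngahic"]).mean())
    merged = cohort_b.join(calls_b["ngahic"], rsuffix="_b")
    col = "ngahic_b" if "ngahic_b" in merged.columns else "ngahic"
    if merged[col].nunique() == 2:
        stat, p = logrank_by_group(merged, col)
    else:
        stat, p = float("nan"), float("nan")
    return {"agreement": agree, "logrank_statistic": float(stat), "logrank_p": float(p)}
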