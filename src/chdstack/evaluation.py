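"""Metrics and the replicated method-comparison protocol.

Reports accuracy, sensitivity, specificity and ROC/AUC for the ensemble
estimators, aggregated as mean +/- SD over R independent replicates. Each
replicate redraws the entire stratified split plan (test set included) —
with a single private cohort, re-randomizing the partition is what gives
the between-replicate SD of test metrics its meaning. All methods within
a replicate run on identical splits (paired design), which only sharpens
the comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score, roc_curve

from .ensemble import (
    EnsembleConfig,
    FittedStack,
    _meta_forest,
    fit_two_step,
    predict_two_step,
)
from .learners import DEFAULT_RETAINED, fit_classifier, get_spec
from .preprocessing import apply_reduction, fit_default_reduction, make_split_plan
from .schema import FeatureTable

__all__ = [
    "ConfusionMetrics",
    "confusion_metrics",
    "ROCCurve",
    "roc_auc",
    "ReplicateReport",
    "run_replicates",
    "glps_only_run",
    "ENSEMBLE_METHODS",
]


@dataclass(frozen=True)
class ConfusionMetrics:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.n

    @property
    def sensitivity(self) -> float:
        """True-positive rate; NaN when truth has no positives."""
        denom = self.tp + self.fn
        return self.tp / denom if denom else float("nan")

    @property
    def specificity(self) -> float:
        """True-negative rate; NaN when truth has no negatives."""
        denom = self.tn + self.fp
        return self.tn / denom if denom else float("nan")


def confusion_metrics(truth, predicted) -> ConfusionMetrics:
    truth = np.asarray(truth).astype(int)
    predicted = np.asarray(predicted).astype(int)
    if truth.shape != predicted.shape:
        raise ValueError("truth and prediction lengths differ")
    if truth.size == 0:
        raise ValueError("empty vectors")
    return ConfusionMetrics(
        tp=int(((truth == 1) & (predicted == 1)).sum()),
        fp=int(((truth == 0) & (predicted == 1)).sum()),
        tn=int(((truth == 0) & (predicted == 0)).sum()),
        fn=int(((truth == 1) & (predicted == 0)).sum()),
    )


@dataclass(frozen=True)
class ROCCurve:
    """Threshold-swept ROC curve with trapezoidal AUC.

    The AUC equals the probability that a random positive outscores a
    random negative, ties counting one half.
    """

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float


def roc_auc(truth, scores) -> ROCCurve:
    truth = np.asarray(truth).astype(int)
    scores = np.asarray(scores, dtype=float)
    if len(np.unique(truth)) < 2:
        raise ValueError("ROC requires both classes in truth")
    fpr, tpr, thr = roc_curve(truth, scores, drop_intermediate=False)
    return ROCCurve(fpr=fpr, tpr=tpr, thresholds=thr,
                    auc=float(roc_auc_score(truth, scores)))


# ---------------------------------------------------------------------------
# replicated comparison protocol

ENSEMBLE_METHODS = (
    "two_step_stacking",
    "traditional_stacking",
    "weighted_voting",
    "majority_voting",
)

_METRICS = ("accuracy", "auc", "sensitivity", "specificity")


@dataclass
class ReplicateReport:
    """Per-replicate metrics per method plus mean/SD aggregation."""

    records: pd.DataFrame  # columns: method, replicate, seed, accuracy, ...
    R: int
    base_seed: int
    config: EnsembleConfig = field(default_factory=EnsembleConfig)

    def summary(self) -> pd.DataFrame:
        """Mean and n-1 SD per method and metric; SD is NaN for R < 2."""
        g = self.records.groupby("method")[list(_METRICS)]
        mean = g.mean().add_suffix("_mean")
        sd = g.std(ddof=1).add_suffix("_sd")
        return mean.join(sd)

    def to_json(self, path) -> None:
        doc = {
            "R": self.R,
            "base_seed": self.base_seed,
            "records": self.records.to_dict(orient="records"),
            "summary": self.summary().reset_index().to_dict(orient="records"),
        }
        import json

        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1)


def _vote_matrix(classifiers, table: FeatureTable) -> np.ndarray:
    return np.column_stack([m.predict(table) for m in classifiers]).astype(float)


def _evaluate(truth, labels, scores) -> dict[str, float]:
    cm = confusion_metrics(truth, labels)
    return {
        "accuracy": cm.accuracy,
        "auc": roc_auc(truth, scores).auc,
        "sensitivity": cm.sensitivity,
        "specificity": cm.specificity,
    }


def _one_replicate(
    table: FeatureTable,
    methods,
    config: EnsembleConfig,
    seed: int,
    pca: bool,
    split_kw: dict,
) -> dict[str, dict[str, float]]:
    plan = make_split_plan(table.labels, K=config.K, seed=seed, **split_kw)
    if pca and table.schema.ste_blocks:
        models = fit_default_reduction(table.subset(plan.train_pool_idx))
        table = apply_reduction(table, models)
    pool = table.subset(plan.train_pool_idx)
    val0 = table.subset(plan.validation0_idx)
    test = table.subset(plan.test_idx)
    specs = [get_spec(n) for n in DEFAULT_RETAINED[: config.L]]
    if len(specs) != config.L:
        raise ValueError(f"cannot assemble L={config.L} classifiers")

    out: dict[str, dict[str, float]] = {}
    flat_methods = [m for m in methods if m != "two_step_stacking"]
    if flat_methods:
        # base classifiers on the full training pool, shared by the
        # one-step methods (paired design)
        fitted = [
            fit_classifier(s, pool, seed=seed + 101 * i, tune=config.tune)
            for i, s in enumerate(specs)
        ]
        V_val = _vote_matrix(fitted, val0)
        V_test = _vote_matrix(fitted, test)
        val_acc = (V_val == val0.labels[:, None]).mean(axis=0)
        for method in flat_methods:
            if method == "traditional_stacking":
                # same fitted bases as the voting methods; only the
                # meta-learner is trained here
                stack = FittedStack(
                    classifiers=fitted,
                    meta=_meta_forest(config.meta_trees, seed + 7),
                    stack_on=config.stack_on,
                    threshold=config.vote_threshold,
                )
                stack.meta.fit(stack.base_matrix(val0), val0.labels)
                scores = stack.predict_score(test)
                labels = (scores >= config.vote_threshold).astype(int)
            elif method == "weighted_voting":
                w = val_acc / val_acc.sum() if val_acc.sum() > 0 else (
                    np.full(config.L, 1.0 / config.L))
                scores = V_test @ w
                labels = (scores >= config.vote_threshold).astype(int)
            elif method == "majority_voting":
                scores = V_test.mean(axis=1)
                labels = (scores >= config.vote_threshold).astype(int)
            else:
                raise ValueError(f"unknown method {method!r}")
            out[method] = _evaluate(test.labels, labels, scores)
    if "two_step_stacking" in methods:
        model = fit_two_step(specs, table, plan, config)
        labels, scores = predict_two_step(model, test)
        out["two_step_stacking"] = _evaluate(test.labels, labels, scores)
    return out


def run_replicates(
    table: FeatureTable,
    methods=ENSEMBLE_METHODS,
    config: EnsembleConfig | None = None,
    R: int = 50,
    base_seed: int = 0,
    pca: bool = True,
    split_kw: dict | None = None,
) -> ReplicateReport:
    """Run the paired method comparison over R redrawn split plans.

    Replicate r uses seed ``base_seed + r`` for its split plan and every
    stochastic learner, so the whole report is reproducible from
    ``base_seed``. PCA (when enabled) is refitted per replicate on that
    replicate's training pool only.
    """
    config = config or EnsembleConfig()
    unknown = set(methods) - set(ENSEMBLE_METHODS)
    if unknown:
        raise ValueError(f"unknown methods {sorted(unknown)}")
    rows = []
    for r in range(1, R + 1):
        seed = base_seed + r
        cfg = EnsembleConfig(
            L=config.L, K=config.K, vote_threshold=config.vote_threshold,
            stack_on=config.stack_on, meta_trees=config.meta_trees,
            tune=config.tune, seed=seed,
        )
        results = _one_replicate(table, methods, cfg, seed, pca,
                                 split_kw or {})
        for method, metrics in results.items():
            rows.append({"method": method, "replicate": r, "seed": seed,
                         **metrics})
    records = pd.DataFrame(rows)
    return ReplicateReport(records=records, R=R, base_seed=base_seed,
                           config=config)


def _one_replicate_curves(
    table: FeatureTable,
    methods=ENSEMBLE_METHODS,
    seed: int = 0,
    config: EnsembleConfig | None = None,
) -> dict[str, ROCCurve]:
    """Test-set ROC curves of each method for a single split plan."""
    config = config or EnsembleConfig(seed=seed)
    plan = make_split_plan(table.labels, K=config.K, seed=seed)
    work = table
    if table.schema.ste_blocks:
        models = fit_default_reduction(table.subset(plan.train_pool_idx))
        work = apply_reduction(table, models)
    test = work.subset(plan.test_idx)
    out = _one_replicate_scores(work, plan, methods, config, seed)
    return {name: roc_auc(test.labels, scores) for name, scores in out.items()}


def _one_replicate_scores(work, plan, methods, config, seed):
    pool = work.subset(plan.train_pool_idx)
    val0 = work.subset(plan.validation0_idx)
    test = work.subset(plan.test_idx)
    specs = [get_spec(n) for n in DEFAULT_RETAINED[: config.L]]
    out: dict[str, np.ndarray] = {}
    flat = [m for m in methods if m != "two_step_stacking"]
    if flat:
        fitted = [fit_classifier(s, pool, seed=seed + 101 * i, tune=config.tune)
                  for i, s in enumerate(specs)]
        V_val = _vote_matrix(fitted, val0)
        V_test = _vote_matrix(fitted, test)
        val_acc = (V_val == val0.labels[:, None]).mean(axis=0)
        for method in flat:
            if method == "traditional_stacking":
                stack = FittedStack(classifiers=fitted,
                                    meta=_meta_forest(config.meta_trees, seed + 7),
                                    stack_on=config.stack_on)
                stack.meta.fit(stack.base_matrix(val0), val0.labels)
                out[method] = stack.predict_score(test)
            elif method == "weighted_voting":
                w = val_acc / val_acc.sum()
                out[method] = V_test @ w
            elif method == "majority_voting":
                out[method] = V_test.mean(axis=1)
    if "two_step_stacking" in methods:
        model = fit_two_step(specs, work, plan, config)
        _, scores = predict_two_step(model, test)
        out["two_step_stacking"] = scores
    return out


def glps_only_run(
    table: FeatureTable,
    config: EnsembleConfig | None = None,
    R: int = 50,
    base_seed: int = 0,
    methods=("two_step_stacking",),
) -> ReplicateReport:
    """The ablation with predictors restricted to the three GLPS layers.

    Identical protocol, no PCA (the GLPS block has only 3 features).
    """
    glps = list(table.schema.glps)
    if len(glps) == 0:
        raise ValueError("schema has no GLPS features")
    restricted = table.select_features(glps)
    return run_replicates(restricted, methods=methods, config=config, R=R,
                          base_seed=base_seed, pca=False)
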