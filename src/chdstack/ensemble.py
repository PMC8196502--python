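"""Ensemble combiners: majority voting, weighted voting, and stacking.

The two-step stacking estimator works over a stratified split plan: for
each of K resampled first-step (train, validation) pairs, L base
classifiers are fitted on the train part and a random-forest meta-learner
is fitted on their validation predictions (a first-step stack). The K
stack outputs on a common held-out validation set ("validation 0") then
train a second random-forest meta-learner. Test subjects are never seen
by any fitting step.

The meta-learners play the role of the stacking "weights": the decision
rule is meta-learner score >= 0.5, with the score defined as the fraction
of forest trees voting positive. Ties at exactly 0.5 classify as
positive, consistent with the >= indicator in all voting rules here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier

from .learners import ClassifierSpec, FittedClassifier, fit_classifier
from .preprocessing import SplitPlan
from .schema import FeatureTable

__all__ = [
    "EnsembleConfig",
    "majority_vote",
    "weighted_vote",
    "FittedStack",
    "fit_stack",
    "TwoStepModel",
    "fit_two_step",
    "predict_two_step",
]


@dataclass
class EnsembleConfig:
    """Knobs of the two-step estimator.

    ``stack_on`` selects what the meta-learners see: hard 0/1 base
    predictions (default, matching the voting formulation) or continuous
    base scores. ``meta_trees`` is the random-forest size of both
    meta-learners.
    """

    L: int = 14
    K: int = 10
    vote_threshold: float = 0.5
    stack_on: str = "labels"  # or "scores"
    meta_trees: int = 500
    tune: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.K < 1 or self.L < 1:
            raise ValueError("K and L must be >= 1")
        if self.stack_on not in ("labels", "scores"):
            raise ValueError("stack_on must be 'labels' or 'scores'")


def _check_votes(votes) -> np.ndarray:
    votes = np.asarray(votes)
    if votes.size == 0:
        raise ValueError("empty vote vector")
    if not np.isin(votes, (0, 1)).all():
        raise ValueError("votes must be 0/1")
    return votes.astype(float)


def majority_vote(votes) -> int:
    """1 iff the mean vote is >= 0.5 (exact ties classify positive)."""
    v = _check_votes(votes)
    return int(v.mean() >= 0.5)


def weighted_vote(votes, weights) -> int:
    """1 iff sum(w_l * c_l) >= 0.5; weights may be negative.

    With all weights equal to 1/L this reduces to :func:`majority_vote`.
    """
    v = _check_votes(votes)
    w = np.asarray(weights, dtype=float)
    if w.shape != v.shape:
        raise ValueError(f"length mismatch: {v.size} votes, {w.size} weights")
    if not np.isfinite(w).all():
        raise ValueError("weights must be finite")
    return int(float(w @ v) >= 0.5)


def _meta_forest(n_trees: int, seed: int) -> RandomForestClassifier:
    # meta inputs are a handful of (near-)binary vote columns from a small
    # validation set; unregularized trees would memorize it, so leaves are
    # kept coarse
    return RandomForestClassifier(
        n_estimators=n_trees,
        random_state=seed % (2**31),
        min_samples_leaf=5,
    )


def _tree_vote_fraction(forest: RandomForestClassifier, Z: np.ndarray) -> np.ndarray:
    """Fraction of trees voting for class 1 (the documented meta score)."""
    if len(forest.classes_) == 1:
        return np.full(Z.shape[0], float(forest.classes_[0]))
    votes = np.stack([t.predict(Z) for t in forest.estimators_])
    # tree predict returns class indices into forest.classes_
    pos_index = list(forest.classes_).index(1)
    return (votes == pos_index).mean(axis=0)


def _assert_disjoint(a: FeatureTable, b: FeatureTable, what: str) -> None:
    overlap = set(a.subject_ids) & set(b.subject_ids)
    if overlap:
        raise ValueError(
            f"leakage: {what} share subjects {sorted(overlap)[:5]}"
        )


@dataclass
class FittedStack:
    """One first-step stack: L fitted base classifiers + a meta-learner."""

    classifiers: list[FittedClassifier]
    meta: RandomForestClassifier
    stack_on: str
    threshold: float = 0.5

    @property
    def L(self) -> int:
        return len(self.classifiers)

    def base_matrix(self, table: FeatureTable) -> np.ndarray:
        if self.stack_on == "scores":
            cols = [m.predict_score(table) for m in self.classifiers]
        else:
            cols = [m.predict(table) for m in self.classifiers]
        return np.column_stack(cols).astype(float)

    def predict_score(self, table: FeatureTable) -> np.ndarray:
        return _tree_vote_fraction(self.meta, self.base_matrix(table))

    def predict(self, table: FeatureTable) -> np.ndarray:
        return (self.predict_score(table) >= self.threshold).astype(int)


def fit_stack(
    specs: list[ClassifierSpec],
    train: FeatureTable,
    validation: FeatureTable,
    config: EnsembleConfig | None = None,
) -> FittedStack:
    """Fit base classifiers on ``train`` and the meta-learner on their
    out-of-sample predictions over ``validation``.

    Train and validation must be disjoint subject sets; overlap raises.
    """
    config = config or EnsembleConfig(L=len(specs))
    _assert_disjoint(train, validation, "train and validation")
    if len(np.unique(validation.labels)) < 2:
        raise ValueError("validation set must contain both classes")
    fitted = [
        fit_classifier(spec, train, seed=config.seed + 101 * i, tune=config.tune)
        for i, spec in enumerate(specs)
    ]
    stack = FittedStack(classifiers=fitted,
                        meta=_meta_forest(config.meta_trees, config.seed + 7),
                        stack_on=config.stack_on,
                        threshold=config.vote_threshold)
    Z = stack.base_matrix(validation)
    stack.meta.fit(Z, validation.labels)
    return stack


@dataclass
class TwoStepModel:
    """K first-step stacks plus the second-step meta-learner."""

    stacks: list[FittedStack]
    meta: RandomForestClassifier
    stack_on: str
    plan: SplitPlan | None = None
    config: EnsembleConfig = field(default_factory=EnsembleConfig)

    @property
    def K(self) -> int:
        return len(self.stacks)

    def first_step_matrix(self, table: FeatureTable) -> np.ndarray:
        if self.stack_on == "scores":
            cols = [s.predict_score(table) for s in self.stacks]
        else:
            cols = [s.predict(table) for s in self.stacks]
        return np.column_stack(cols).astype(float)


def fit_two_step(
    specs: list[ClassifierSpec],
    table: FeatureTable,
    plan: SplitPlan,
    config: EnsembleConfig | None = None,
) -> TwoStepModel:
    """Fit the two-step stacking estimator over a split plan.

    For k = 1..K a first-step stack is fitted on the k-th (train,
    validation) pair; the second-step meta-learner is then fitted on the K
    stack outputs over validation 0. Subjects in ``plan.test_idx`` are
    never used in any fit.
    """
    config = config or EnsembleConfig(L=len(specs), K=plan.K)
    if plan.K != config.K:
        raise ValueError(f"plan has K={plan.K} but config K={config.K}")
    if len(specs) != config.L:
        raise ValueError(f"{len(specs)} specs but config L={config.L}")
    val0 = table.subset(plan.validation0_idx)
    stacks = []
    for k, (train_idx, val_idx) in enumerate(plan.first_step_splits):
        cfg_k = EnsembleConfig(
            L=config.L, K=config.K, vote_threshold=config.vote_threshold,
            stack_on=config.stack_on, meta_trees=config.meta_trees,
            tune=config.tune, seed=config.seed + 1000 * (k + 1),
        )
        stacks.append(
            fit_stack(specs, table.subset(train_idx), table.subset(val_idx), cfg_k)
        )
    model = TwoStepModel(
        stacks=stacks,
        meta=_meta_forest(config.meta_trees, config.seed + 13),
        stack_on=config.stack_on,
        plan=plan,
        config=config,
    )
    Z0 = model.first_step_matrix(val0)
    model.meta.fit(Z0, val0.labels)
    return model


def predict_two_step(
    model: TwoStepModel, table: FeatureTable
) -> tuple[np.ndarray, np.ndarray]:
    """(labels, scores) of the two-step estimator on new subjects.

    The score is the second-step meta-learner's tree-vote fraction; the
    label is score >= 0.5, with exact ties positive.
    """
    Z = model.first_step_matrix(table)
    scores = _tree_vote_fraction(model.meta, Z)
    labels = (scores >= model.config.vote_threshold).astype(int)
    return labels, scores
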