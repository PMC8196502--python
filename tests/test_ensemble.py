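import itertools

import numpy as np
import pytest

from chdstack.ensemble import (
    EnsembleConfig,
    TwoStepModel,
    _meta_forest,
    fit_stack,
    fit_two_step,
    majority_vote,
    predict_two_step,
    weighted_vote,
)
from chdstack.learners import get_spec
from chdstack.preprocessing import make_split_plan
from chdstack.synthetic import GeneratorParams, default_params, generate_cohort


class TestVoting:
    @pytest.mark.parametrize("votes,expected", [
        ([1, 1, 0], 1),
        ([0, 1, 0, 1], 1),   # exact tie: the >= 0.5 indicator is positive
        ([0, 0, 0], 0),
        ([1], 1),
        ([0, 0, 1], 0),
    ])
    def test_majority_vote(self, votes, expected):
        assert majority_vote(votes) == expected

    @pytest.mark.parametrize("votes,weights,expected", [
        ([1, 0], [0.7, 0.3], 1),
        ([1, 1, 0], [-0.2, 0.9, 0.3], 1),  # negative weights admissible
        ([1, 1], [0.2, 0.2], 0),
        ([1], [0.5], 1),                   # boundary: sum exactly 0.5
    ])
    def test_weighted_vote(self, votes, weights, expected):
        assert weighted_vote(votes, weights) == expected

    def test_equal_weights_reduce_to_majority_exhaustive(self):
        """All 2^L patterns for L <= 10: weights 1/L == majority vote."""
        for L in range(1, 11):
            w = [1.0 / L] * L
            for votes in itertools.product((0, 1), repeat=L):
                assert weighted_vote(votes, w) == majority_vote(votes)

    def test_nonbinary_vote_rejected(self):
        with pytest.raises(ValueError):
            majority_vote([0, 2])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            weighted_vote([1, 0], [1.0])

    def test_empty_votes_rejected(self):
        with pytest.raises(ValueError):
            majority_vote([])


SMALL_SPECS = ["logistic regression", "LDA", "naive Bayes"]


@pytest.fixture(scope="module")
def separable_cohort():
    """Cohort with a very large class effect: essentially separable."""
    effects = {k: 0.0 for k in GeneratorParams().class_effect}
    effects.update({"PSS": 3.0, "SSR": 3.0, "GLPS": 3.0})
    return generate_cohort(default_params(n_subjects=200, seed=19,
                                          class_effect=effects))


class TestFitStack:
    def test_leakage_guard(self, cohort_small):
        a = cohort_small.subset(np.arange(40))
        b = cohort_small.subset(np.arange(30, 60))  # overlap 30..39
        with pytest.raises(ValueError, match="leakage"):
            fit_stack([get_spec(n) for n in SMALL_SPECS], a, b)

    def test_single_classifier_stack_reduces_to_base(self, separable_cohort):
        """L=1 on separable data: the meta-learner reproduces the base
        classifier's predictions."""
        train = separable_cohort.subset(np.arange(120))
        val = separable_cohort.subset(np.arange(120, 160))
        probe = separable_cohort.subset(np.arange(160, 200))
        cfg = EnsembleConfig(L=1, seed=0)
        stack = fit_stack([get_spec("logistic regression")], train, val, cfg)
        base = stack.classifiers[0]
        assert np.array_equal(stack.predict(probe), base.predict(probe))

    def test_meta_learner_can_copy_the_oracle_column(self, separable_cohort):
        """Bases = {always-1, always-0, oracle}: stack accuracy on the
        validation set equals the oracle's."""
        from chdstack.learners import FittedClassifier

        train = separable_cohort.subset(np.arange(120))
        val = separable_cohort.subset(np.arange(120, 200))
        oracle = fit_stack([get_spec("logistic regression")], train, val,
                           EnsembleConfig(L=1, seed=1)).classifiers[0]

        class Constant:
            def __init__(self, c):
                self.c = c
                self.classes_ = np.array([0, 1])

            def predict(self, X):
                return np.full(len(X), self.c)

            def predict_proba(self, X):
                p = np.zeros((len(X), 2))
                p[:, self.c] = 1.0
                return p

        def const(c):
            return FittedClassifier(
                spec_name=f"always-{c}", pipeline=Constant(c),
                feature_names=oracle.feature_names, best_params={},
                cv_accuracy=None)

        from chdstack.ensemble import FittedStack, _meta_forest

        stack = FittedStack(classifiers=[const(1), const(0), oracle],
                            meta=_meta_forest(200, 3), stack_on="labels")
        stack.meta.fit(stack.base_matrix(val), val.labels)
        acc_stack = (stack.predict(val) == val.labels).mean()
        acc_oracle = (oracle.predict(val) == val.labels).mean()
        assert acc_stack == pytest.approx(acc_oracle, abs=0.01)

    def test_validation_single_class_rejected(self, cohort_small):
        train = cohort_small.subset(np.arange(40))
        vidx = 40 + np.flatnonzero(cohort_small.labels[40:] == 1)
        with pytest.raises(ValueError):
            fit_stack([get_spec("LDA")], train, cohort_small.subset(vidx))


@pytest.fixture(scope="module")
def fitted(separable_cohort):
    plan = make_split_plan(separable_cohort.labels, K=3, seed=5)
    specs = [get_spec(n) for n in SMALL_SPECS]
    cfg = EnsembleConfig(L=3, K=3, seed=5)
    model = fit_two_step(specs, separable_cohort, plan, cfg)
    return separable_cohort, plan, model


class TestTwoStep:
    def test_structure(self, fitted):
        _, plan, model = fitted
        assert model.K == 3
        assert all(s.L == 3 for s in model.stacks)
        assert model.meta.n_features_in_ == 3

    def test_separable_test_accuracy_is_one(self, fitted):
        table, plan, model = fitted
        test = table.subset(plan.test_idx)
        labels, scores = predict_two_step(model, test)
        assert (labels == test.labels).all()

    def test_unanimous_stacks_decide(self, fitted):
        table, plan, model = fitted
        test = table.subset(plan.test_idx)
        Z = model.first_step_matrix(test)
        labels, _ = predict_two_step(model, test)
        for i in range(len(test)):
            if np.all(Z[i] == 1):
                assert labels[i] == 1
            elif np.all(Z[i] == 0):
                assert labels[i] == 0

    def test_k1_reduces_to_single_stack(self, separable_cohort):
        """K=1: two-step test predictions equal the single stack's."""
        plan = make_split_plan(separable_cohort.labels, K=1, seed=9)
        specs = [get_spec(n) for n in SMALL_SPECS]
        cfg = EnsembleConfig(L=3, K=1, seed=9)
        model = fit_two_step(specs, separable_cohort, plan, cfg)
        test = separable_cohort.subset(plan.test_idx)
        labels, _ = predict_two_step(model, test)
        assert np.array_equal(labels, model.stacks[0].predict(test))

    def test_k_mismatch_rejected(self, separable_cohort):
        plan = make_split_plan(separable_cohort.labels, K=2, seed=1)
        with pytest.raises(ValueError, match="K"):
            fit_two_step([get_spec(n) for n in SMALL_SPECS],
                         separable_cohort, plan,
                         EnsembleConfig(L=3, K=5, seed=1))

    def test_stack_order_permutation_equivariance(self, fitted):
        """Permuting the K stacks and refitting the second-step meta-learner
        on the permuted columns leaves predictions unchanged."""
        table, plan, model = fitted
        test = table.subset(plan.test_idx)
        val0 = table.subset(plan.validation0_idx)
        base_labels, _ = predict_two_step(model, test)

        perm = [2, 0, 1]
        permuted = TwoStepModel(
            stacks=[model.stacks[i] for i in perm],
            meta=_meta_forest(model.config.meta_trees, model.config.seed + 13),
            stack_on=model.stack_on,
            plan=plan,
            config=model.config,
        )
        permuted.meta.fit(permuted.first_step_matrix(val0), val0.labels)
        labels, _ = predict_two_step(permuted, test)
        assert np.array_equal(labels, base_labels)

    def test_test_subjects_never_influence_fit(self, separable_cohort):
        """Corrupting test-subject features changes no fitted parameter."""
        plan = make_split_plan(separable_cohort.labels, K=2, seed=3)
        specs = [get_spec(n) for n in SMALL_SPECS]

        def fit_and_fingerprint(table):
            model = fit_two_step(specs, table, plan,
                                 EnsembleConfig(L=3, K=2, seed=3))
            probe = table.subset(plan.validation0_idx)
            return np.concatenate(
                [s.predict_score(probe) for s in model.stacks])

        corrupted = separable_cohort.subset(np.arange(len(separable_cohort)))
        cols = corrupted.features.columns[:5]
        corrupted.features.loc[plan.test_idx, cols] += 1000.0
        assert np.array_equal(fit_and_fingerprint(separable_cohort),
                              fit_and_fingerprint(corrupted))
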