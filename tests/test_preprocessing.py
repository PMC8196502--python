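import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chdstack.preprocessing import (
    apply_reduction,
    choose_components,
    fit_block_pca,
    fit_default_reduction,
    make_split_plan,
    ttest_screen,
)
from chdstack.schema import count_predictors
from chdstack.synthetic import default_params, generate_cohort
from tests.conftest import make_toy_table


def welch_oracle(a, b):
    """Textbook Welch t and p, coded independently of scipy."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = len(a), len(b)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    se2 = va / na + vb / nb
    t = (a.mean() - b.mean()) / np.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    from scipy.stats import t as tdist

    p = 2 * tdist.sf(abs(t), df)
    return t, p


class TestTTestScreen:
    def test_symmetric_classes_give_t_zero(self):
        X = np.array([[1.0], [2.0], [3.0], [1.0], [2.0], [3.0]])
        t = make_toy_table(X, [1, 1, 1, 0, 0, 0])
        rep = ttest_screen(t, features=["f0"])
        assert rep.loc["f0", "t"] == pytest.approx(0.0)
        assert rep.loc["f0", "p"] == pytest.approx(1.0)

    def test_extreme_separation_flagged(self):
        rng = np.random.default_rng(0)
        X = np.r_[np.zeros(4), np.ones(4)].reshape(-1, 1) + rng.normal(
            0, 1e-6, (8, 1))
        t = make_toy_table(X, [0] * 4 + [1] * 4)
        rep = ttest_screen(t)
        assert rep.loc["f0", "p"] < 0.05
        assert rep.loc["f0", "flagged"].item()

    def test_welch_textbook_example(self):
        # group A {1..5} vs B {3..7}: Welch t = -2.0, p ~ 0.0805
        X = np.r_[[1, 2, 3, 4, 5], [3, 4, 5, 6, 7]].reshape(-1, 1).astype(float)
        t = make_toy_table(X, [0] * 5 + [1] * 5)
        rep = ttest_screen(t)  # t is positive class minus handled by scipy sign
        assert abs(rep.loc["f0", "t"]) == pytest.approx(2.0, abs=1e-12)
        assert rep.loc["f0", "p"] == pytest.approx(0.08051, abs=5e-5)
        assert not rep.loc["f0", "flagged"].item()

    def test_zero_variance_both_classes_p_one(self):
        X = np.full((8, 1), 3.0)
        t = make_toy_table(X, [0] * 4 + [1] * 4)
        rep = ttest_screen(t)
        assert rep.loc["f0", "p"] == 1.0
        assert rep.loc["f0", "degenerate"].item()

    def test_agrees_with_hand_coded_welch(self):
        """50 random small samples: screen matches the independent Welch
        formula to 1e-10."""
        rng = np.random.default_rng(42)
        for _ in range(50):
            na, nb = rng.integers(3, 20, size=2)
            a = rng.normal(rng.uniform(-1, 1), rng.uniform(0.5, 2), na)
            b = rng.normal(rng.uniform(-1, 1), rng.uniform(0.5, 2), nb)
            X = np.r_[a, b].reshape(-1, 1)
            t = make_toy_table(X, [1] * na + [0] * nb)
            rep = ttest_screen(t)
            t_exp, p_exp = welch_oracle(a, b)
            assert rep.loc["f0", "t"] == pytest.approx(t_exp, abs=1e-10)
            assert rep.loc["f0", "p"] == pytest.approx(p_exp, abs=1e-10)

    def test_pooled_variant_differs_for_unequal_variances(self):
        rng = np.random.default_rng(3)
        X = np.r_[rng.normal(0, 1, 10), rng.normal(0.5, 4, 25)].reshape(-1, 1)
        t = make_toy_table(X, [1] * 10 + [0] * 25)
        pw = ttest_screen(t, variant="welch").loc["f0", "p"]
        pp = ttest_screen(t, variant="pooled").loc["f0", "p"]
        assert pw != pytest.approx(pp, abs=1e-6)


class TestBlockPCA:
    def test_perfectly_correlated_block(self, cohort_small):
        t = cohort_small
        base = t.features["PSS_seg01"].to_numpy()
        for name in t.schema.ste_blocks["PSS"]:
            t.features[name] = base * 1.0
        # covariance PCA: correlation PCA cannot standardize equal columns
        model = fit_block_pca(t, "PSS", 1, standardize=False)
        ev = model.eigenvalues
        assert ev[0] / ev.sum() == pytest.approx(1.0, abs=1e-8)

    def test_isotropic_data_flat_spectrum(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(20_000, 3))
        t = make_toy_table(X, [0, 1] * 10_000)
        model = fit_block_pca(t, ["f0", "f1", "f2"], 2)
        assert np.max(model.eigenvalues) / np.min(model.eigenvalues) < 1.15

    def test_two_feature_toy_first_loading(self):
        # points on the diagonal plus orthogonal jitter: first loading is
        # (1,1)/sqrt(2); oracle from the 2x2 eigenproblem solved by hand
        d = np.array([1.0, 2.0, 3.0, 4.0])
        jit = np.array([0.05, -0.05, -0.05, 0.05])  # sample-orthogonal to d
        X = np.c_[d + jit, d - jit]
        t = make_toy_table(X, [0, 1, 0, 1])
        model = fit_block_pca(t, ["f0", "f1"], 1, standardize=False)
        assert model.loadings[:, 0] == pytest.approx([1 / np.sqrt(2)] * 2,
                                                     abs=1e-8)

    def test_loadings_orthonormal(self, cohort424):
        model = fit_block_pca(cohort424, "SSR", 5)
        G = model.loadings.T @ model.loadings
        assert np.allclose(G, np.eye(G.shape[0]), atol=1e-8)
        assert np.all(np.diff(model.eigenvalues) <= 1e-12)
        assert np.all(model.eigenvalues >= 0)

    def test_sign_convention_stable(self, cohort424):
        m1 = fit_block_pca(cohort424, "TP", 3)
        m2 = fit_block_pca(cohort424, "TP", 3)
        assert np.array_equal(m1.loadings, m2.loadings)
        largest = np.abs(m1.loadings).argmax(axis=0)
        assert np.all(m1.loadings[largest, np.arange(m1.loadings.shape[1])] > 0)

    def test_too_many_components_rejected(self, cohort424):
        with pytest.raises(ValueError):
            fit_block_pca(cohort424, "PSS", 18)

    def test_reconstruction_error_decreases_with_components(self, cohort424):
        X = cohort424.features[list(cohort424.schema.ste_blocks["PSS"])].to_numpy()
        errs = []
        for k in (1, 3, 6, 10, 17):
            m = fit_block_pca(cohort424, "PSS", k)
            Z = (X - m.mean) / m.scale
            W = m.loadings[:, :k]
            errs.append(np.sum((Z - Z @ W @ W.T) ** 2))
        assert all(a >= b - 1e-9 for a, b in zip(errs, errs[1:]))


class TestChooseComponents:
    @pytest.mark.parametrize("block,expected", [("PSS", 3), ("SSR", 3), ("TP", 2)])
    def test_fixed_rule(self, block, expected):
        assert choose_components([5, 4, 3, 2, 1], "fixed", block=block) == expected

    def test_elbow_dominant_first_drop(self):
        assert choose_components([10, 1, 0.9, 0.8], "elbow") == 1

    def test_elbow_later_drop(self):
        assert choose_components([10, 9.5, 9, 1, 0.9], "elbow") == 3

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            choose_components([], "fixed", block="PSS")

    def test_increasing_rejected(self):
        with pytest.raises(ValueError):
            choose_components([1, 2], "elbow")


class TestApplyReduction:
    def test_default_reduction_28_predictors(self, cohort424):
        models = fit_default_reduction(cohort424)
        red = apply_reduction(cohort424, models)
        assert count_predictors(red.schema)[0] == 28

    def test_zero_component_edge(self, cohort424):
        models = fit_default_reduction(
            cohort424, fixed_counts={"PSS": 0, "SSR": 0, "TP": 0})
        red = apply_reduction(cohort424, models)
        assert count_predictors(red.schema)[0] == 20

    def test_training_scores_centered(self, cohort424):
        models = fit_default_reduction(cohort424)
        red = apply_reduction(cohort424, models)
        for m in models:
            for c in m.component_names:
                assert abs(red.features[c].mean()) < 1e-8

    def test_projection_of_held_out_subjects(self, cohort424):
        train = cohort424.subset(np.arange(300))
        rest = cohort424.subset(np.arange(300, 424))
        models = fit_default_reduction(train)
        red = apply_reduction(rest, models)
        # held-out scores are generally not centered
        assert len(red) == 124

    def test_block_mismatch_rejected(self, cohort424):
        models = fit_default_reduction(cohort424)
        models[0].feature_names = models[0].feature_names[::-1]
        with pytest.raises(ValueError):
            apply_reduction(cohort424, models)


class TestSplitPlan:
    def test_study_design_arithmetic(self):
        labels = np.r_[np.ones(217, int), np.zeros(207, int)]
        plan = make_split_plan(labels, 0.15, 0.20, 0.20, K=10, seed=0)
        assert len(plan.test_idx) == 64
        assert len(plan.validation0_idx) == 72
        assert len(plan.train_pool_idx) == 288
        assert all(len(tr) == 230 and len(va) == 58
                   for tr, va in plan.first_step_splits)
        assert plan.K == 10

    def test_small_balanced_stratification(self):
        labels = np.r_[np.ones(5, int), np.zeros(5, int)]
        plan = make_split_plan(labels, test_frac=0.2, K=2, seed=1)
        assert len(plan.test_idx) == 2
        assert labels[plan.test_idx].sum() == 1

    def test_deterministic(self):
        labels = np.r_[np.ones(60, int), np.zeros(50, int)]
        a = make_split_plan(labels, K=3, seed=7)
        b = make_split_plan(labels, K=3, seed=7)
        assert np.array_equal(a.test_idx, b.test_idx)
        for (t1, v1), (t2, v2) in zip(a.first_step_splits, b.first_step_splits):
            assert np.array_equal(t1, t2) and np.array_equal(v1, v2)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        n1=st.integers(30, 120),
        n0=st.integers(30, 120),
        seed=st.integers(0, 10_000),
    )
    def test_parts_disjoint_exhaustive(self, n1, n0, seed):
        labels = np.r_[np.ones(n1, int), np.zeros(n0, int)]
        plan = make_split_plan(labels, K=3, seed=seed)
        parts = [plan.test_idx, plan.validation0_idx, plan.train_pool_idx]
        allidx = np.concatenate(parts)
        assert len(allidx) == n1 + n0
        assert len(np.unique(allidx)) == n1 + n0
        for tr, va in plan.first_step_splits:
            sub = np.concatenate([tr, va])
            assert sorted(sub) == sorted(plan.train_pool_idx)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(n1=st.integers(40, 150), n0=st.integers(40, 150),
           seed=st.integers(0, 1000))
    def test_class_ratio_within_one_subject(self, n1, n0, seed):
        labels = np.r_[np.ones(n1, int), np.zeros(n0, int)]
        plan = make_split_plan(labels, K=2, seed=seed)
        total_ratio = n1 / (n1 + n0)
        for part in (plan.test_idx, plan.validation0_idx, plan.train_pool_idx):
            n_pos = labels[part].sum()
            # within 1 subject per class of the stratified target
            assert abs(n_pos - total_ratio * len(part)) <= 1 + 1e-9

    def test_tiny_stratum_errors(self):
        labels = np.r_[np.ones(2, int), np.zeros(50, int)]
        with pytest.raises(ValueError):
            make_split_plan(labels, test_frac=0.15, K=2, seed=0)

    def test_json_roundtrip(self, tmp_path):
        labels = np.r_[np.ones(40, int), np.zeros(40, int)]
        plan = make_split_plan(labels, K=2, seed=3)
        p = tmp_path / "plan.json"
        plan.to_json(p)
        from chdstack.preprocessing import SplitPlan

        back = SplitPlan.from_json(p)
        assert np.array_equal(back.test_idx, plan.test_idx)
        assert back.params == plan.params
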