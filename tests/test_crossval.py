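import numpy as np
import pandas as pd
import pytest

from gliorad.crossval import (
    EnetConfig,
    SvmConfig,
    apply_platt,
    enet_select,
    fit_platt,
    make_folds,
    posterior_from_decision,
    run_nested_cv,
    stability_count,
    svm_tune_train,
)
from gliorad.synthetic import generate_feature_table


class TestMakeFolds:
    def test_study_size_partition(self):
        labels = np.array([1] * 93 + [0] * 71)
        assignment = make_folds(labels, k=10, seed=3)
        sizes = np.bincount(assignment)
        assert set(sizes) <= {16, 17}
        assert sizes.sum() == 164
        # stratification: every fold has both classes
        for f in range(10):
            assert len(set(labels[assignment == f])) == 2

    def test_leave_one_out(self):
        labels = np.array([0, 1] * 5)
        assignment = make_folds(labels, k=10, seed=0)
        assert sorted(np.bincount(assignment)) == [1] * 10

    def test_deterministic(self):
        labels = np.array([0, 1] * 20)
        a = make_folds(labels, 5, seed=9)
        b = make_folds(labels, 5, seed=9)
        np.testing.assert_array_equal(a, b)

    def test_class_smaller_than_k_errors(self):
        labels = np.array([1] * 3 + [0] * 30)
        with pytest.raises(ValueError, match="smaller k"):
            make_folds(labels, k=5, seed=0)


class TestEnetSelect:
    def test_strong_single_feature_is_found(self):
        cfg = EnetConfig(alpha_grid=(0.5, 1.0), n_lambdas=20, inner_folds=5)
        hits = 0
        for seed in range(3):
            t = generate_feature_table(100, 51, 1, effect_size=5.0, seed=seed,
                                       prevalence=0.5)
            selected, _, _ = enet_select(t.drop(columns="label"), t["label"], cfg, seed)
            hits += "inf_000" in selected
        assert hits == 3

    def test_pure_ridge_selects_everything(self):
        cfg = EnetConfig(alpha_grid=(0.0,), n_lambdas=10, inner_folds=4)
        t = generate_feature_table(40, 12, 1, 1.0, seed=0, prevalence=0.5)
        selected, alpha, _ = enet_select(t.drop(columns="label"), t["label"], cfg, 0)
        assert alpha == 0.0
        assert len(selected) == 12

    def test_null_selection_is_sparse_under_one_se(self):
        cfg = EnetConfig(alpha_grid=(0.5,), n_lambdas=15, criterion="1se",
                         inner_folds=5)
        rng = np.random.default_rng(0)
        sizes = []
        for seed in range(5):
            t = generate_feature_table(60, 100, 0, 0.0, seed=seed, prevalence=0.5)
            t["label"] = rng.permutation(t["label"].to_numpy())
            import warnings

            with warnings.catch_warnings():
                # the null usually triggers the empty-selection fallback
                warnings.simplefilter("ignore", UserWarning)
                selected, _, _ = enet_select(
                    t.drop(columns="label"), t["label"], cfg, seed
                )
            sizes.append(len(selected))
        assert np.median(sizes) <= 2

    def test_constant_labels_error(self):
        t = generate_feature_table(20, 5, 0, 0.0, seed=0, prevalence=0.5)
        t["label"] = 1
        with pytest.raises(ValueError):
            enet_select(t.drop(columns="label"), t["label"])


class TestSvmTuneTrain:
    def _separable(self, n=40):
        rng = np.random.default_rng(1)
        x = np.vstack([rng.normal(-5, 1, (n // 2, 2)), rng.normal(5, 1, (n // 2, 2))])
        y = np.array([0] * (n // 2) + [1] * (n // 2))
        return pd.DataFrame(x, columns=["a", "b"]), y

    def test_separable_toy_perfect_training_accuracy(self):
        x, y = self._separable()
        cfg = SvmConfig(inner_folds=5)
        svm = svm_tune_train(x, y, cfg, seed=0)
        pred = (svm.decision_values(x.to_numpy()) > 0).astype(int)
        assert (pred == y).all()

    def test_chosen_point_in_grids(self):
        x, y = self._separable()
        cfg = SvmConfig(box_constraint_grid=(0.5, 2.0), kernel_scale_grid=(1.0, 3.0),
                        inner_folds=4)
        svm = svm_tune_train(x, y, cfg, seed=0)
        assert svm.box_constraint in cfg.box_constraint_grid
        assert svm.kernel_scale in cfg.kernel_scale_grid

    def test_xor_is_not_linearly_separable(self):
        rng = np.random.default_rng(2)
        centers = np.array([[-3, -3], [3, 3], [-3, 3], [3, -3]])
        x = np.vstack([rng.normal(c, 0.5, (10, 2)) for c in centers])
        y = np.array([0] * 20 + [1] * 20)
        svm = svm_tune_train(pd.DataFrame(x, columns=["a", "b"]), y,
                             SvmConfig(inner_folds=4), seed=0)
        pred = (svm.decision_values(x) > 0).astype(int)
        assert (pred == y).mean() <= 0.75

    def test_empty_feature_set_errors(self):
        with pytest.raises(ValueError):
            svm_tune_train(pd.DataFrame(index=range(10)), np.zeros(10, dtype=int))


class TestPlatt:
    def test_symmetric_calibration_gives_half_at_zero(self):
        f = np.array([-2.0, -1.0, 1.0, 2.0])
        y = np.array([0, 0, 1, 1])
        a, b = fit_platt(f, y)
        assert a < 0
        assert apply_platt(np.array([0.0]), a, b)[0] == pytest.approx(0.5, abs=0.05)

    def test_posterior_strictly_increasing_in_decision(self, rng):
        f = rng.normal(size=100)
        y = (f + rng.normal(0, 0.5, 100) > 0).astype(int)
        a, b = fit_platt(f, y)
        grid = np.linspace(-3, 3, 50)
        p = apply_platt(grid, a, b)
        assert np.all(np.diff(p) > 0)

    def test_separated_toy_calibrates_to_correct_side(self, rng):
        f = np.concatenate([rng.normal(-3, 0.5, 30), rng.normal(3, 0.5, 30)])
        y = np.array([0] * 30 + [1] * 30)
        p = posterior_from_decision(f, y)
        assert ((p > 0.5).astype(int) == y).all()

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            fit_platt(np.ones(5), np.ones(5, dtype=int))


class TestNestedCv:
    @pytest.fixture(scope="class")
    def small_result(self):
        table = generate_feature_table(60, 40, 4, effect_size=1.5, seed=4,
                                       prevalence=0.5)
        enet = EnetConfig(alpha_grid=(0.5, 1.0), n_lambdas=15, inner_folds=5)
        svm = SvmConfig(box_constraint_grid=(1.0, 100.0),
                        kernel_scale_grid=(1.0, 10.0), inner_folds=4)
        return table, run_nested_cv(table, enet_cfg=enet, svm_cfg=svm, k=5, seed=4)

    def test_partition_covers_each_subject_once(self, small_result):
        _, res = small_result
        seen = np.concatenate([f.test_indices for f in res.folds])
        assert sorted(seen) == list(range(60))
        assert not np.isnan(res.pooled_posteriors).any()

    def test_no_subject_in_own_training_fold(self, small_result):
        _, res = small_result
        for f in res.folds:
            assert not set(f.test_indices) & set(f.train_indices)

    def test_leakage_audit_selection_recomputable_from_training_only(
        self, small_result
    ):
        """Refitting the selector on the logged training partition alone
        reproduces the fold's selection exactly."""
        table, res = small_result
        enet = EnetConfig(alpha_grid=(0.5, 1.0), n_lambdas=15, inner_folds=5)
        f = res.folds[0]
        x = table.drop(columns="label")
        y = table["label"].to_numpy()
        inner_seed = (4 * 100003 + f.fold * 7919 + 1) % (2**31)
        redo, alpha, lam = enet_select(
            x.iloc[f.train_indices].reset_index(drop=True),
            y[f.train_indices],
            enet,
            inner_seed,
        )
        assert redo == f.selected_features
        assert (alpha, lam) == (f.alpha, f.lam)

    def test_deterministic_given_seed(self, small_result):
        table, res = small_result
        enet = EnetConfig(alpha_grid=(0.5, 1.0), n_lambdas=15, inner_folds=5)
        svm = SvmConfig(box_constraint_grid=(1.0, 100.0),
                        kernel_scale_grid=(1.0, 10.0), inner_folds=4)
        res2 = run_nested_cv(table, enet_cfg=enet, svm_cfg=svm, k=5, seed=4)
        np.testing.assert_array_equal(res.pooled_posteriors, res2.pooled_posteriors)
        assert [f.selected_features for f in res.folds] == [
            f.selected_features for f in res2.folds
        ]

    def test_selection_counts_bounded_by_k(self, small_result):
        _, res = small_result
        assert all(0 < c <= 5 for c in res.stability_counts.values())

    def test_result_serializes(self, small_result):
        import json

        _, res = small_result
        blob = json.dumps(res.to_dict())
        assert "stability" in blob


class TestStabilityCount:
    def _result_with_counts(self, counts):
        from gliorad.crossval import NestedCvResult

        return NestedCvResult(
            folds=[], pooled_posteriors=np.zeros(1), pooled_decisions=np.zeros(1),
            labels=np.zeros(1, dtype=int), feature_names=[], stability_counts=counts,
        )

    def test_nine_of_ten_retained_eight_excluded(self):
        res = self._result_with_counts({"keep": 9, "drop": 8, "top": 10})
        names = [n for n, _ in stability_count(res, threshold=9)]
        assert names == ["top", "keep"]

    def test_no_feature_reaches_threshold(self):
        res = self._result_with_counts({"a": 3})
        assert stability_count(res, threshold=9) == []

    def test_threshold_zero_returns_all_selected(self):
        res = self._result_with_counts({"a": 1, "b": 5})
        assert [n for n, _ in stability_count(res, threshold=0)] == ["b", "a"]

    def test_single_candidate_column_is_the_stable_set(self):
        """d=1 informative column with a huge effect: every fold selects it."""
        table = generate_feature_table(40, 1, 1, effect_size=5.0, seed=0,
                                       prevalence=0.5)
        enet = EnetConfig(alpha_grid=(1.0,), n_lambdas=10, inner_folds=4)
        svm = SvmConfig(box_constraint_grid=(1.0,), kernel_scale_grid=(1.0,),
                        inner_folds=3)
        res = run_nested_cv(table, enet_cfg=enet, svm_cfg=svm, k=4, seed=0)
        assert [n for n, _ in stability_count(res, threshold=4)] == ["inf_000"]
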