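"""Nested cross-validation: fold planning, tuning, metrics, pooling,
and the structural no-leakage guarantee."""

import numpy as np
import pandas as pd
import pytest

from peptidia.cohort import CohortConfig, generate_cohort
from peptidia.containers import ValidationError
from peptidia.models import ModelSpec
from peptidia.nested import (
    SelectionSettings,
    aggregate_folds,
    compute_metrics,
    fit_predict_outer,
    make_outer_folds,
    pool_gray_zone,
    pool_outer_predictions,
    run_nested_cv,
    tune_inner,
)
from peptidia.preprocess import run_preprocess
from tests.conftest import make_annotation


class TestFoldPlan:
    def test_paper_composition_gives_35_35_35_35_34(self):
        _, ann = generate_cohort(CohortConfig(seed=0))
        for seed in (0, 1, 2):
            plan = make_outer_folds(ann, 5, seed=seed)
            assert sorted(plan.fold_sizes()) == [34, 35, 35, 35, 35]

    def test_k_one_single_fold(self):
        ann = make_annotation(["Active"] * 5 + ["Remission"] * 5)
        plan = make_outer_folds(ann, 1, seed=0)
        assert plan.fold_sizes() == [10]

    def test_per_cell_counts_within_one_of_proportional(self):
        acts = ["Active"] * 10 + ["Remission"] * 10
        fc = [500.0] * 8 + [150.0] * 2 + [50.0] * 8 + [150.0] * 2
        ann = make_annotation(acts, fc=fc)  # cells (8, 2, 8, 2)
        plan = make_outer_folds(ann, 4, seed=3)
        df = pd.DataFrame({"fold": plan.assignments, "cell": plan.cells})
        for cell, grp in df.groupby("cell"):
            counts = grp.fold.value_counts().reindex(range(4), fill_value=0)
            n = len(grp)
            assert counts.max() - counts.min() <= 1
            assert counts.between(n // 4, -(-n // 4)).all()

    def test_folds_partition_samples(self):
        _, ann = generate_cohort(CohortConfig(seed=1))
        plan = make_outer_folds(ann, 5, seed=0)
        all_ids = sorted(sum((plan.fold_samples(f) for f in range(5)), []))
        assert all_ids == sorted(ann.sample_ids)

    def test_small_cell_warns_not_fails(self):
        acts = ["Active"] * 6 + ["Remission"] * 6
        fc = [150.0] + [500.0] * 5 + [50.0] * 6  # one gray-zone Active sample
        ann = make_annotation(acts, fc=fc)
        with pytest.warns(UserWarning, match="fewer samples"):
            plan = make_outer_folds(ann, 3, seed=0)
        assert sum(plan.fold_sizes()) == 12


class TestMetrics:
    def test_perfect_predictions(self):
        m = compute_metrics([1, 1, 0, 0], [0.9, 0.8, 0.1, 0.2])
        assert all(m[k] == 1.0 for k in m)

    def test_hand_confusion_table(self):
        # TP=9 FN=4 TN=19 FP=2
        y = [1] * 13 + [0] * 21
        prob = [0.9] * 9 + [0.1] * 4 + [0.1] * 19 + [0.9] * 2
        m = compute_metrics(y, prob)
        assert m["Sensitivity"] == pytest.approx(9 / 13)
        assert m["Specificity"] == pytest.approx(19 / 21)
        assert m["F1"] == pytest.approx(0.75)
        assert m["Accuracy"] == pytest.approx(28 / 34)
        assert m["BalancedAccuracy"] == pytest.approx((9 / 13 + 19 / 21) / 2)

    def test_constant_probability_auc_half(self):
        m = compute_metrics([1, 0, 1, 0], [0.5] * 4)
        assert m["AUC"] == pytest.approx(0.5)

    def test_single_class_auc_nan_with_warning(self):
        with pytest.warns(UserWarning, match="AUC undefined"):
            m = compute_metrics([1, 1, 1], [0.9, 0.8, 0.7])
        assert np.isnan(m["AUC"])


class TestAggregate:
    def test_identical_folds_zero_sd(self):
        df = pd.DataFrame({"AUC": [0.9] * 5})
        out = aggregate_folds(df)
        assert out.loc["AUC", "mean"] == pytest.approx(0.9)
        assert out.loc["AUC", "sd"] == 0.0

    def test_textbook_formulas(self):
        v = np.array([0.81, 0.95, 0.77, 0.9, 0.88])
        out = aggregate_folds(pd.DataFrame({"m": v}))
        assert out.loc["m", "mean"] == pytest.approx(v.mean())
        assert out.loc["m", "sd"] == pytest.approx(
            np.sqrt(((v - v.mean()) ** 2).sum() / (len(v) - 1))
        )


class TestPooling:
    @staticmethod
    def _pred(y, p):
        return pd.DataFrame(
            {"sample_id": [f"S{i}" for i in range(len(y))], "fold": 0,
             "y_true": y, "prob": p}
        )

    def test_perfect_ranking(self):
        pooled = pool_outer_predictions(self._pred([1, 1, 0, 0], [0.9, 0.8, 0.2, 0.1]))
        assert pooled["roc_auc"] == 1.0
        assert pooled["pr_auc"] == 1.0

    def test_auc_equals_concordant_pair_count(self):
        y = [1, 0, 1, 0, 1, 0]
        p = [0.9, 0.8, 0.7, 0.3, 0.2, 0.1]
        pooled = pool_outer_predictions(self._pred(y, p))
        pos = [pi for pi, yi in zip(p, y) if yi == 1]
        neg = [pi for pi, yi in zip(p, y) if yi == 0]
        conc = sum(
            1.0 if a > b else 0.5 if a == b else 0.0 for a in pos for b in neg
        )
        assert pooled["roc_auc"] == pytest.approx(conc / (len(pos) * len(neg)))

    def test_random_scores_auc_near_half(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, 2000)
        p = rng.random(2000)
        pooled = pool_outer_predictions(self._pred(y, p))
        assert pooled["roc_auc"] == pytest.approx(0.5, abs=0.03)

    def test_duplicate_sample_rejected(self):
        df = self._pred([1, 0], [0.9, 0.1])
        df.loc[1, "sample_id"] = "S0"
        with pytest.raises(ValidationError, match="more than once"):
            pool_outer_predictions(df)

    def test_gray_zone_pooling_delegates_to_metrics(self):
        acts = ["Active"] * 4 + ["Remission"] * 4
        fc = [150.0, 150.0, 500.0, 500.0, 150.0, 150.0, 50.0, 50.0]
        ann = make_annotation(acts, fc=fc)
        y = [1, 1, 1, 1, 0, 0, 0, 0]
        p = [0.9, 0.4, 0.8, 0.9, 0.2, 0.6, 0.1, 0.2]
        preds = self._pred(y, p)
        out = pool_gray_zone(preds, ann)
        assert out["n"] == 4  # S0, S1, S4, S5 are gray
        sub = preds[preds.sample_id.isin(["S0", "S1", "S4", "S5"])]
        expected = compute_metrics(sub.y_true.to_numpy(), sub.prob.to_numpy())
        assert out["metrics"] == expected

    def test_no_gray_samples_empty_report(self):
        ann = make_annotation(["Active", "Remission"], fc=[500.0, 50.0])
        out = pool_gray_zone(self._pred([1, 0], [0.9, 0.1]), ann)
        assert out == {"n": 0, "metrics": {}}


class TestTuneAndFit:
    def _toy(self, seed=0, n=40, p=4):
        rng = np.random.default_rng(seed)
        y = np.r_[np.ones(n // 2), np.zeros(n // 2)].astype(int)
        X = rng.normal(0, 1, (n, p))
        X[:, 0] += 3.0 * y
        return X, y

    def test_single_grid_point_returned(self):
        X, y = self._toy()
        spec = ModelSpec("gaussian_nb", grid=[{"var_smoothing": 1e-8}])
        hp, table = tune_inner(X, y, spec, seed=0)
        assert hp == {"var_smoothing": 1e-8}
        assert (table["inner_fold"] == -1).sum() == 1

    def test_separable_toy_linear_svm_inner_auc_one(self):
        rng = np.random.default_rng(0)
        n = 40
        y = np.r_[np.ones(n // 2), np.zeros(n // 2)].astype(int)
        X = rng.normal(0, 0.1, (n, 2))
        X[:, 0] += 5.0 * y
        spec = ModelSpec("svm_linear", grid=[{"C": 1.0}])
        _, table = tune_inner(X, y, spec, seed=0)
        assert table.loc[table.inner_fold == -1, "AUC"].iloc[0] == 1.0

    def test_correlated_pair_ridge_shares_weight(self):
        """Two identical informative features under a ridge-leaning mixing
        parameter get near-equal coefficients."""
        rng = np.random.default_rng(1)
        n = 100
        y = np.r_[np.ones(50), np.zeros(50)].astype(int)
        signal = 2.0 * y + rng.normal(0, 1, n)
        X = np.column_stack([signal, signal, rng.normal(0, 1, (n, 3))])
        spec = ModelSpec("elastic_net_logistic", grid=[{"l1_ratio": 0.0, "C": 0.5}])
        hp, _ = tune_inner(X, y, spec, seed=0)
        prob, est = fit_predict_outer(X, y, X[:5], spec, hp, seed=0)
        coef = est[-1].coef_.ravel()
        assert coef[0] == pytest.approx(coef[1], rel=0.2)
        assert abs(coef[0]) > 0

    def test_refit_reproducible_to_1e8(self):
        X, y = self._toy(seed=3, n=30)
        spec = ModelSpec("elastic_net_logistic", grid=[{"l1_ratio": 0.5, "C": 1.0}])
        p1, _ = fit_predict_outer(X, y, X[:7], spec, spec.grid[0], seed=5)
        p2, _ = fit_predict_outer(X, y, X[:7], spec, spec.grid[0], seed=5)
        np.testing.assert_allclose(p1, p2, atol=1e-8)

    def test_schema_mismatch_rejected(self):
        X, y = self._toy()
        spec = ModelSpec("gaussian_nb", grid=[{"var_smoothing": 1e-9}])
        with pytest.raises(ValidationError, match="mismatch"):
            fit_predict_outer(X, y, X[:, :2], spec, spec.grid[0], seed=0)

    def test_inner_cv_needs_enough_class_members(self):
        rng = np.random.default_rng(0)
        X = rng.normal(0, 1, (10, 3))
        y = np.r_[np.ones(3), np.zeros(7)].astype(int)
        with pytest.raises(ValidationError, match="inner 5-fold"):
            tune_inner(X, y, ModelSpec("gaussian_nb"), seed=0)


@pytest.fixture(scope="module")
def prepared(small_cohort):
    matrix, ann = small_cohort
    pep = run_preprocess(matrix, ann)
    return pep, ann.loc(pep.sample_ids)


class TestNestedRun:
    def _run(self, pep, ann, seed=4):
        return run_nested_cv(
            pep,
            ann,
            specs=[ModelSpec("gaussian_nb")],
            selection=SelectionSettings(methods=("l1_logistic",), n_repeats=5),
            seed=seed,
        )

    def test_every_sample_predicted_exactly_once(self, prepared):
        pep, ann = prepared
        res = self._run(pep, ann)
        preds = res.reports["gaussian_nb"].predictions
        assert sorted(preds.sample_id) == sorted(ann.sample_ids)

    def test_noising_outer_test_rows_changes_nothing_upstream(self, prepared):
        """Leakage audit: replacing held-out rows with noise leaves the
        selected panels, chosen hyperparameters and fitted models
        untouched; only predictions differ."""
        pep, ann = prepared
        base = self._run(pep, ann)
        rng = np.random.default_rng(99)
        fold0_test = base.fold_plan.fold_samples(0)
        noised = pep.intensities.copy()
        noised.loc[:, fold0_test] = rng.normal(0, 1, (pep.n_features, len(fold0_test)))
        res2 = run_nested_cv(
            pep.with_values(noised),
            ann,
            specs=[ModelSpec("gaussian_nb")],
            selection=SelectionSettings(methods=("l1_logistic",), n_repeats=5),
            seed=4,
        )
        for p1, p2 in zip(base.panels, res2.panels):
            if p1.fold_index == 0:
                assert p1.stable_features == p2.stable_features
        rec1 = [r for r in base.models if r.fold == 0][0]
        rec2 = [r for r in res2.models if r.fold == 0][0]
        assert rec1.chosen_hp == rec2.chosen_hp
        assert rec1.panel == rec2.panel
        assert rec1.inner_auc == rec2.inner_auc

    def test_incomplete_matrix_rejected(self, small_cohort):
        matrix, ann = small_cohort
        with pytest.raises(ValidationError, match="complete"):
            run_nested_cv(matrix, ann.loc(matrix.sample_ids), seed=0)
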