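"""Stability-ensemble selection: selector behavior on planted signals,
the retention-frequency rule, and the cross-fold consensus rule."""

import numpy as np
import pandas as pd
import pytest

from peptidia.containers import ValidationError
from peptidia.selection import (
    ConsensusPanel,
    SelectionRun,
    StablePanel,
    boruta_select,
    build_consensus,
    l1_logistic_select,
    panel_from_runs,
    rfe_svm_select,
    run_fold_selection,
)


class TestBoruta:
    def test_perfect_separator_confirmed(self):
        rng = np.random.default_rng(0)
        n = 60
        y = np.r_[np.ones(n // 2), np.zeros(n // 2)].astype(int)
        X = rng.normal(0, 1, (n, 51))
        X[:, 0] = y
        res = boruta_select(X, y, max_iter=30, n_trees=100, seed=1)
        assert 0 in res["selected"]
        assert res["decisions"][0] == "Confirmed"

    def test_pure_noise_confirms_nothing(self):
        rng = np.random.default_rng(1)
        y = np.r_[np.ones(70), np.zeros(70)].astype(int)
        confirmed = []
        for seed in range(3):
            X = np.random.default_rng(seed).normal(0, 1, (140, 100))
            res = boruta_select(X, y, max_iter=25, n_trees=100, seed=seed)
            confirmed.append(len(res["selected"]))
        assert sum(n == 0 for n in confirmed) >= 2

    def test_xor_pair_found_by_boruta_not_lasso(self):
        """Jointly informative, marginally null pair: the forest wrapper
        confirms both while the linear lasso sees nothing."""
        boruta_hits = lasso_hits = 0
        for seed in range(3):
            rng = np.random.default_rng(seed)
            n = 240
            a = rng.integers(0, 2, n)
            b = rng.integers(0, 2, n)
            y = (a ^ b).astype(int)
            X = np.column_stack(
                [a + rng.normal(0, 0.1, n), b + rng.normal(0, 0.1, n), rng.normal(0, 1, (n, 6))]
            )
            res = boruta_select(X, y, max_iter=40, n_trees=200, seed=seed)
            if {0, 1} <= set(res["selected"]):
                boruta_hits += 1
            lsel = set(l1_logistic_select(X, y, seed=seed))
            if not ({0, 1} & lsel):
                lasso_hits += 1
        assert boruta_hits >= 2
        assert lasso_hits >= 2

    def test_degenerate_y_rejected(self):
        with pytest.raises(ValidationError):
            boruta_select(np.ones((10, 3)), np.ones(10), seed=0)


class TestL1Logistic:
    def test_dominant_signal_always_selected(self):
        for seed in range(3):
            rng = np.random.default_rng(seed)
            n = 140
            y = np.r_[np.ones(53), np.zeros(87)].astype(int)
            X = rng.normal(0, 1, (n, 100))
            X[:, 0] += 3.0 * y
            assert 0 in l1_logistic_select(X, y, seed=seed)

    def test_pure_noise_selects_few(self):
        sizes = []
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            y = np.r_[np.ones(70), np.zeros(70)].astype(int)
            X = rng.normal(0, 1, (140, 100))
            sizes.append(len(l1_logistic_select(X, y, seed=seed)))
        assert np.mean(sizes) <= 5.0  # <= 5% of features on average

    def test_near_orthogonal_design_selects_top_marginal_scores(self):
        """With (near-)orthogonal standardized features the lasso's active
        set at any penalty is the top-k by |marginal score| |x_j'(y - ybar)|."""
        rng = np.random.default_rng(0)
        n, p = 256, 8
        X = np.linalg.qr(rng.normal(size=(n, p)))[0] * np.sqrt(n)
        beta = np.array([2.0, 1.5, 1.0, 0.0, 0.0, 0.0, 0.0, 0.0])
        y = (X @ beta + rng.normal(0, 1, n) > 0).astype(int)
        sel = l1_logistic_select(X, y, seed=1)
        scores = np.abs(X.T @ (y - y.mean()))
        top = set(np.argsort(-scores)[: len(sel)])
        assert set(sel) == top

    def test_constant_columns_dropped_not_fatal(self):
        rng = np.random.default_rng(0)
        y = np.r_[np.ones(30), np.zeros(30)].astype(int)
        X = rng.normal(0, 1, (60, 5))
        X[:, 2] = 7.0
        X[:, 0] += 2.5 * y
        sel = l1_logistic_select(X, y, seed=0)
        assert 2 not in sel
        assert 0 in sel


class TestRfeSvm:
    def test_full_size_returns_everything(self):
        rng = np.random.default_rng(0)
        y = np.r_[np.ones(20), np.zeros(20)].astype(int)
        X = rng.normal(0, 1, (40, 12))
        assert rfe_svm_select(X, y, subset_sizes=(12,), seed=0) == list(range(12))

    def test_two_informative_among_98_nulls(self):
        hits = 0
        for seed in range(3):
            rng = np.random.default_rng(seed)
            n = 140
            y = np.r_[np.ones(70), np.zeros(70)].astype(int)
            X = rng.normal(0, 1, (n, 100))
            X[:, 0] += 2.0 * y
            X[:, 1] += 2.0 * y
            sel = rfe_svm_select(X, y, subset_sizes=(2, 5, 10), seed=seed)
            if {0, 1} <= set(sel):
                hits += 1
        assert hits >= 3 * 95 // 100  # all three at this effect size

    def test_duplicated_informative_feature_keeps_a_copy(self):
        rng = np.random.default_rng(2)
        n = 80
        y = np.r_[np.ones(40), np.zeros(40)].astype(int)
        signal = 2.0 * y + rng.normal(0, 1, n)
        X = np.column_stack([signal, signal, rng.normal(0, 1, (n, 20))])
        sel = rfe_svm_select(X, y, subset_sizes=(2, 5), seed=0)
        assert {0, 1} & set(sel)

    def test_empty_sizes_rejected(self):
        with pytest.raises(ValidationError):
            rfe_svm_select(np.ones((10, 3)), np.r_[np.ones(5), np.zeros(5)], subset_sizes=())


class TestRetentionRule:
    features = pd.Index([f"F{i}" for i in range(6)])

    @staticmethod
    def _runs(per_method_counts):
        """Build a run log where feature Fi is selected in counts[m][i]
        of 10 repeats for method m."""
        runs = []
        for method, counts in per_method_counts.items():
            for rep in range(1, 11):
                sel = [f"F{i}" for i, c in enumerate(counts) if rep <= c]
                runs.append(SelectionRun(method, rep, 0, sel))
        return runs

    def test_seven_of_ten_in_six_of_ten_out(self):
        runs = self._runs({"boruta": [7, 6, 0, 0, 0, 0]})
        panel = panel_from_runs(self.features, runs, 10, methods=("boruta",))
        assert panel.stable_features == ["F0"]
        assert panel.frequencies.loc["F1", "boruta"] == pytest.approx(0.6)

    def test_union_across_methods(self):
        runs = self._runs(
            {"boruta": [10, 0, 0, 0, 0, 0], "l1_logistic": [0, 8, 0, 0, 0, 0],
             "rfe_svm": [0, 0, 7, 5, 0, 0]}
        )
        panel = panel_from_runs(self.features, runs, 10)
        assert panel.stable_features == ["F0", "F1", "F2"]

    def test_pooled_mode_uses_single_frequency(self):
        runs = self._runs(
            {"boruta": [10, 10, 0, 0, 0, 0], "l1_logistic": [10, 6, 0, 0, 0, 0],
             "rfe_svm": [10, 4, 0, 0, 0, 0]}
        )
        panel = panel_from_runs(self.features, runs, 10, pool_methods=True)
        # F1 pooled frequency (10+6+4)/30 = 2/3 < 0.7
        assert panel.stable_features == ["F0"]

    def test_hand_log_matches_exhaustive_rule(self):
        rng = np.random.default_rng(0)
        counts = {m: rng.integers(0, 11, 6).tolist() for m in ("boruta", "l1_logistic", "rfe_svm")}
        runs = self._runs(counts)
        panel = panel_from_runs(self.features, runs, 10)
        expected = sorted(
            {
                f"F{i}"
                for m, cs in counts.items()
                for i, c in enumerate(cs)
                if c / 10 >= 0.7
            }
        )
        assert panel.stable_features == expected

    def test_all_empty_runs_give_empty_panel(self):
        runs = [SelectionRun(m, r, 0, []) for m in ("boruta", "l1_logistic") for r in range(1, 11)]
        panel = panel_from_runs(self.features, runs, 10, methods=("boruta", "l1_logistic"))
        assert panel.stable_features == []


class TestRunFoldSelection:
    def test_stratified_subsample_guard(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame(rng.normal(0, 1, (10, 4)))
        y = np.r_[np.ones(2), np.zeros(8)].astype(int)
        with pytest.raises(ValidationError, match="< 2 samples"):
            run_fold_selection(X, y, subsample_frac=0.5, seed=0, methods=("l1_logistic",))

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(1)
        n = 60
        y = np.r_[np.ones(30), np.zeros(30)].astype(int)
        X = pd.DataFrame(rng.normal(0, 1, (n, 20)))
        X[0] += 2.5 * y
        a = run_fold_selection(X, y, n_repeats=3, seed=7, methods=("l1_logistic",))
        b = run_fold_selection(X, y, n_repeats=3, seed=7, methods=("l1_logistic",))
        assert a.frequencies.equals(b.frequencies)
        assert a.stable_features == b.stable_features


class TestConsensus:
    @staticmethod
    def _panels(sets):
        return [
            StablePanel(fold_index=i, frequencies=pd.DataFrame(), stable_features=sorted(s))
            for i, s in enumerate(sets)
        ]

    def test_three_of_five_in_two_of_five_out(self):
        panels = self._panels([{"A", "B"}, {"A", "B"}, {"A"}, {"C"}, {"C"}])
        cons = build_consensus(panels, min_folds=3)
        assert cons.consensus_features == ["A"]
        assert cons.fold_counts["B"] == 2
        assert cons.fold_counts["C"] == 2

    def test_identical_panels_pass_through(self):
        panels = self._panels([{"A", "B", "C"}] * 5)
        cons = build_consensus(panels)
        assert cons.consensus_features == ["A", "B", "C"]

    def test_empty_input_empty_panel(self):
        cons = build_consensus([])
        assert cons.consensus_features == []
        assert isinstance(cons, ConsensusPanel)
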