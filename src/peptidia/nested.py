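"""Nested 5x5 cross-validation with leakage-free stability selection.

Outer folds are stratified on the joint Activity x Gray-zone cell so
every fold carries its share of the diagnostically hard calprotectin
gray-zone samples. Within each outer-training set: stability-ensemble
feature selection -> inner 5-fold hyperparameter tuning on the stable
panel -> a single refit on the full outer-training set -> one-shot
prediction of the held-out fold. Metrics are reported per fold
(mean ± SD across the five folds), pooled over the concatenated
outer-test predictions (ROC / PR), and pooled over the gray-zone subset
alone.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import (
    average_precision_score,
    precision_recall_curve,
    roc_auc_score,
    roc_curve,
)

from peptidia.containers import (
    ACTIVE,
    PeptideMatrix,
    SampleAnnotation,
    ValidationError,
    check_aligned,
)
from peptidia.models import (
    ModelSpec,
    default_specs,
    linear_coefficients,
    make_estimator,
    resolve_hp,
)
from peptidia.selection import ConsensusPanel, StablePanel, build_consensus, run_fold_selection

METRICS = ("Accuracy", "Sensitivity", "Specificity", "F1", "BalancedAccuracy", "AUC")


# ---------------------------------------------------------------- fold plan


@dataclass
class FoldPlan:
    """Outer-fold assignment with its stratification cells."""

    assignments: pd.Series  # sample_id -> fold index (0-based)
    cells: pd.Series  # sample_id -> joint stratification cell
    k: int
    seed: int | None

    def fold_samples(self, fold: int) -> list:
        return list(self.assignments.index[self.assignments == fold])

    def fold_sizes(self) -> list[int]:
        return [int((self.assignments == f).sum()) for f in range(self.k)]


def make_outer_folds(annotation: SampleAnnotation, k: int = 5, seed: int | None = None) -> FoldPlan:
    """Joint-stratified outer folds with balanced totals.

    Each Activity x Gray cell is split proportionally (per-fold counts
    within ±1 of proportional allocation); cell remainders go to the
    currently smallest folds, so on the 174-sample study composition the
    outer-test folds come out at sizes {35, 35, 35, 35, 34}."""
    cells = annotation.strat_cells()
    if cells.empty:
        raise ValidationError("empty annotation")
    rng = np.random.default_rng(seed)
    assignments = pd.Series(-1, index=cells.index, dtype=int)
    totals = np.zeros(k, dtype=int)
    for cell in sorted(cells.unique()):
        ids = cells.index[cells == cell].to_numpy()
        if len(ids) < k:
            warnings.warn(
                f"stratification cell {cell!r} has fewer samples ({len(ids)}) than folds ({k})",
                stacklevel=2,
            )
        ids = rng.permutation(ids)
        base, rem = divmod(len(ids), k)
        counts = np.full(k, base, dtype=int)
        if rem:
            order = np.lexsort((np.arange(k), totals))  # smallest fold first, index tie-break
            counts[order[:rem]] += 1
        pos = 0
        for f in range(k):
            assignments.loc[ids[pos : pos + counts[f]]] = f
            pos += counts[f]
        totals += counts
    return FoldPlan(assignments=assignments, cells=cells, k=k, seed=seed)


# ------------------------------------------------------------------ metrics


def compute_metrics(y_true, prob, threshold: float = 0.5) -> dict:
    """Binary metrics with Active (label 1) as the positive class.

    Sensitivity = recall of Active, Specificity = recall of Remission,
    F1 on Active; AUC is the Mann–Whitney statistic of the probabilities
    (tied scores get half credit). A single-class ``y_true`` yields
    ``AUC = nan`` with a warning."""
    y = np.asarray(y_true, dtype=int)
    p = np.asarray(prob, dtype=float)
    pred = (p >= threshold).astype(int)
    tp = int(((pred == 1) & (y == 1)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    n_pos, n_neg = tp + fn, tn + fp
    sens = tp / n_pos if n_pos else float("nan")
    spec = tn / n_neg if n_neg else float("nan")
    f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 0.0
    if n_pos and n_neg:
        auc = float(roc_auc_score(y, p))
    else:
        warnings.warn("single-class y_true: AUC undefined", stacklevel=2)
        auc = float("nan")
    return {
        "Accuracy": (tp + tn) / len(y),
        "Sensitivity": sens,
        "Specificity": spec,
        "F1": f1,
        "BalancedAccuracy": (sens + spec) / 2.0,
        "AUC": auc,
    }


def aggregate_folds(per_fold: pd.DataFrame) -> pd.DataFrame:
    """Mean and sample SD (ddof=1) of each metric across outer folds."""
    return pd.DataFrame({"mean": per_fold.mean(axis=0), "sd": per_fold.std(axis=0, ddof=1)})


def pool_outer_predictions(predictions: pd.DataFrame) -> dict:
    """Pooled ROC / PR over the concatenated outer-test predictions.

    ``predictions`` needs columns ``sample_id``, ``y_true``, ``prob``;
    every sample must appear exactly once."""
    if predictions["sample_id"].duplicated().any():
        dup = predictions.loc[predictions["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValidationError(f"sample(s) predicted more than once: {dup[:5]}")
    y = predictions["y_true"].to_numpy(dtype=int)
    p = predictions["prob"].to_numpy(dtype=float)
    fpr, tpr, roc_thr = roc_curve(y, p)
    prec, rec, pr_thr = precision_recall_curve(y, p)
    return {
        "roc": pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": roc_thr}),
        "pr": pd.DataFrame({"recall": rec, "precision": prec}),
        "roc_auc": float(roc_auc_score(y, p)),
        "pr_auc": float(average_precision_score(y, p)),
    }


def pool_gray_zone(predictions: pd.DataFrame, annotation: SampleAnnotation) -> dict:
    """Metrics on the concatenated gray-zone outer-test predictions."""
    gray_ids = annotation.table.index[annotation.table["gray_zone"]]
    sub = predictions[predictions["sample_id"].isin(gray_ids)]
    if sub.empty:
        return {"n": 0, "metrics": {}}
    return {
        "n": int(len(sub)),
        "metrics": compute_metrics(sub["y_true"].to_numpy(), sub["prob"].to_numpy()),
    }


# ------------------------------------------------------------------- tuning


def _inner_folds(y: np.ndarray, k_inner: int, seed) -> list[tuple[np.ndarray, np.ndarray]]:
    from sklearn.model_selection import StratifiedKFold

    _, counts = np.unique(y, return_counts=True)
    if counts.min() < k_inner:
        raise ValidationError(
            f"inner {k_inner}-fold CV impossible: smallest class has {counts.min()} samples"
        )
    cv = StratifiedKFold(n_splits=k_inner, shuffle=True, random_state=seed)
    return list(cv.split(np.zeros(len(y)), y))


def tune_inner(
    X_train: np.ndarray,
    y_train: np.ndarray,
    spec: ModelSpec,
    k_inner: int = 5,
    seed: int | None = None,
) -> tuple[dict, pd.DataFrame]:
    """Inner stratified k-fold grid search.

    Winner = highest mean inner AUC, ties broken by higher balanced
    accuracy then by grid order; returns the resolved hyperparameters
    and the full inner metric table."""
    X = np.asarray(X_train, dtype=float)
    y = np.asarray(y_train, dtype=int)
    splits = _inner_folds(y, k_inner, seed)
    rows = []
    for gi, hp in enumerate(spec.grid):
        hp_r = resolve_hp(spec.family, hp, X)
        aucs, baccs = [], []
        for fi, (tr, va) in enumerate(splits):
            est = make_estimator(spec.family, hp_r, seed=seed)
            est.fit(X[tr], y[tr])
            prob = est.predict_proba(X[va])[:, 1]
            m = compute_metrics(y[va], prob, threshold=spec.threshold)
            aucs.append(m["AUC"])
            baccs.append(m["BalancedAccuracy"])
            rows.append({"grid_index": gi, "inner_fold": fi, **hp_r, "AUC": m["AUC"],
                         "BalancedAccuracy": m["BalancedAccuracy"]})
        rows.append(
            {
                "grid_index": gi,
                "inner_fold": -1,  # -1 = mean over inner folds
                **hp_r,
                "AUC": float(np.mean(aucs)),
                "BalancedAccuracy": float(np.mean(baccs)),
            }
        )
    table = pd.DataFrame(rows)
    means = table[table["inner_fold"] == -1].set_index("grid_index")
    best = min(
        means.index,
        key=lambda g: (-means.loc[g, "AUC"], -means.loc[g, "BalancedAccuracy"], g),
    )
    chosen = resolve_hp(spec.family, spec.grid[int(best)], X)
    return chosen, table


def fit_predict_outer(
    X_outer_train: np.ndarray,
    y_train: np.ndarray,
    X_outer_test: np.ndarray,
    spec: ModelSpec,
    chosen_hp: dict,
    seed: int | None = None,
):
    """Refit on the full outer-training set; one-shot test predictions.

    Returns (probabilities of Active on the test set, fitted estimator)."""
    X_tr = np.asarray(X_outer_train, dtype=float)
    X_te = np.asarray(X_outer_test, dtype=float)
    if X_tr.shape[1] != X_te.shape[1]:
        raise ValidationError(
            f"train/test feature mismatch: {X_tr.shape[1]} vs {X_te.shape[1]} columns"
        )
    est = make_estimator(spec.family, chosen_hp, seed=seed)
    est.fit(X_tr, np.asarray(y_train, dtype=int))
    return est.predict_proba(X_te)[:, 1], est


# -------------------------------------------------------------- orchestration


@dataclass
class FoldModelRecord:
    fold: int
    family: str
    chosen_hp: dict
    inner_table: pd.DataFrame = field(repr=False)
    inner_auc: float
    coefficients: np.ndarray | None
    intercept: float | None
    panel: list


@dataclass
class EvaluationReport:
    family: str
    per_fold: pd.DataFrame  # fold x metric
    summary: pd.DataFrame  # metric x (mean, sd)
    predictions: pd.DataFrame  # sample_id, fold, y_true, prob, pred
    pooled: dict  # roc, pr, roc_auc, pr_auc
    gray_zone: dict  # n, metrics
    inner_auc: list[float]  # chosen-hp mean inner AUC per fold


@dataclass
class NestedResult:
    fold_plan: FoldPlan
    panels: list[StablePanel]
    consensus: ConsensusPanel
    reports: dict[str, EvaluationReport]
    models: list[FoldModelRecord]


@dataclass
class SelectionSettings:
    """Knobs for per-fold stability selection inside the nested loop.

    ``enabled=False`` short-circuits selection (every feature enters the
    panel) — useful for structural checks of the evaluation machinery."""

    enabled: bool = True
    n_repeats: int = 10
    subsample_frac: float = 0.8
    retention_threshold: float = 0.7
    min_folds: int = 3
    methods: tuple[str, ...] = ("boruta", "l1_logistic", "rfe_svm")
    method_params: dict | None = None
    pool_methods: bool = False


def run_nested_cv(
    matrix: PeptideMatrix,
    annotation: SampleAnnotation,
    specs: list[ModelSpec] | None = None,
    selection: SelectionSettings | None = None,
    k_outer: int = 5,
    k_inner: int = 5,
    seed: int = 0,
) -> NestedResult:
    """The full nested procedure on a complete peptide-level matrix.

    A single integer seed drives fold construction, subsampling, every
    selector and every estimator; identical inputs give identical
    results. Outer-test rows are never visible to selection, tuning or
    fitting."""
    check_aligned(matrix, annotation)
    if matrix.missing_mask.to_numpy().any():
        raise ValidationError("nested CV requires a complete matrix (impute first)")
    specs = specs if specs is not None else default_specs()
    selection = selection or SelectionSettings()

    X_all = matrix.intensities.T  # samples x features
    ann = annotation.loc(X_all.index)
    y_all = ann.y()

    ss = np.random.SeedSequence(seed)
    plan_seed, *fold_seeds = [int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(k_outer + 1)]
    plan = make_outer_folds(ann, k=k_outer, seed=plan_seed)

    panels: list[StablePanel] = []
    records: list[FoldModelRecord] = []
    pred_rows: dict[str, list] = {s.family: [] for s in specs}

    for fold in range(k_outer):
        test_ids = plan.fold_samples(fold)
        train_ids = [s for s in X_all.index if s not in set(test_ids)]
        X_tr_full, y_tr = X_all.loc[train_ids], ann.y(train_ids)
        fseed = fold_seeds[fold]

        if selection.enabled:
            panel_obj = run_fold_selection(
                X_tr_full,
                y_tr,
                n_repeats=selection.n_repeats,
                subsample_frac=selection.subsample_frac,
                retention_threshold=selection.retention_threshold,
                seed=fseed,
                fold_index=fold,
                methods=selection.methods,
                method_params=selection.method_params,
                pool_methods=selection.pool_methods,
            )
        else:
            panel_obj = StablePanel(
                fold_index=fold,
                frequencies=pd.DataFrame(1.0, index=X_all.columns, columns=["all"]),
                stable_features=list(X_all.columns),
            )
        panels.append(panel_obj)
        panel = panel_obj.stable_features
        if not panel:
            raise ValidationError(f"fold {fold}: stability selection returned an empty panel")

        X_tr = X_tr_full[panel].to_numpy(dtype=float)
        X_te = X_all.loc[test_ids, panel].to_numpy(dtype=float)
        y_te = ann.y(test_ids)

        for spec in specs:
            hp, table = tune_inner(X_tr, y_tr, spec, k_inner=k_inner, seed=fseed)
            means = table[table["inner_fold"] == -1]
            hp_keys = [k for k in hp if k in means.columns]
            row = means
            for k in hp_keys:
                row = row[row[k] == hp[k]]
            inner_auc = float(row["AUC"].iloc[0])
            prob, est = fit_predict_outer(X_tr, y_tr, X_te, spec, hp, seed=fseed)
            lin = linear_coefficients(est, spec.family)
            records.append(
                FoldModelRecord(
                    fold=fold,
                    family=spec.family,
                    chosen_hp=hp,
                    inner_table=table,
                    inner_auc=inner_auc,
                    coefficients=None if lin is None else lin[0],
                    intercept=None if lin is None else lin[1],
                    panel=list(panel),
                )
            )
            for sid, yt, pr in zip(test_ids, y_te, prob):
                pred_rows[spec.family].append(
                    {
                        "sample_id": sid,
                        "fold": fold,
                        "y_true": int(yt),
                        "prob": float(pr),
                        "pred": int(pr >= spec.threshold),
                    }
                )

    consensus = build_consensus(
        panels,
        min_folds=selection.min_folds,
        feature_annotation=matrix.feature_annotation,
    )

    reports: dict[str, EvaluationReport] = {}
    for spec in specs:
        preds = pd.DataFrame(pred_rows[spec.family])
        per_fold = pd.DataFrame(
            [
                compute_metrics(
                    preds.loc[preds["fold"] == f, "y_true"],
                    preds.loc[preds["fold"] == f, "prob"],
                )
                for f in range(k_outer)
            ],
            index=pd.RangeIndex(k_outer, name="fold"),
        )[list(METRICS)]
        reports[spec.family] = EvaluationReport(
            family=spec.family,
            per_fold=per_fold,
            summary=aggregate_folds(per_fold),
            predictions=preds,
            pooled=pool_outer_predictions(preds),
            gray_zone=pool_gray_zone(preds, ann),
            inner_auc=[r.inner_auc for r in records if r.family == spec.family],
        )

    return NestedResult(
        fold_plan=plan, panels=panels, consensus=consensus, reports=reports, models=records
    )
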