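"""Stability-ensemble feature selection.

Three complementary selectors — Boruta (all-relevant random-forest
wrapper with shadow features), L1-penalized logistic regression (sparse
directional profile) and recursive feature elimination under a linear
SVM (margin-based ranking) — are each run on repeated class-stratified
80% subsamples of an *outer-training* set. A feature enters the fold's
stable panel when some selector retains it in >= 70% of the repeats; the
consensus signature keeps features stable in >= 3 of the 5 outer folds.

The operations only ever receive training data: leakage from held-out
test folds is structurally impossible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import binomtest
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import balanced_accuracy_score
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import LinearSVC

from peptidia.containers import ValidationError

logger = logging.getLogger(__name__)

CONFIRMED, REJECTED, TENTATIVE = "Confirmed", "Rejected", "Tentative"
METHODS = ("boruta", "l1_logistic", "rfe_svm")


def _check_xy(X: np.ndarray, y: np.ndarray) -> None:
    if X.ndim != 2 or X.shape[1] < 1:
        raise ValidationError("X must be 2-D with >= 1 feature")
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValidationError("y is degenerate: a single class")
    if counts.min() < 2:
        raise ValidationError("need >= 2 samples per class")


def boruta_select(
    X,
    y,
    max_iter: int = 100,
    p_threshold: float = 0.01,
    n_trees: int = 500,
    seed: int | None = None,
) -> dict:
    """Boruta all-relevant selection.

    Each iteration appends an independently shuffled shadow copy of
    every still-undecided feature, fits a random forest, and counts a
    "hit" for each real feature whose importance beats the best shadow.
    Hit counts are tested against Binomial(iters, 1/2) two-sided at
    ``p_threshold``: significantly many hits confirms a feature,
    significantly few rejects it (rejected features leave the design).
    Features still Tentative after ``max_iter`` are treated as not
    selected.

    Returns ``{"decisions": {feature_index: status}, "selected": [...]}``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    _check_xy(X, y)
    rng = np.random.default_rng(seed)
    p = X.shape[1]
    status = np.array([TENTATIVE] * p, dtype=object)
    hits = np.zeros(p, dtype=int)
    trials = 0

    for _ in range(max_iter):
        tentative = np.where(status == TENTATIVE)[0]
        if tentative.size == 0:
            break
        keep = np.where(status != REJECTED)[0]
        shadows = X[:, tentative].copy()
        for j in range(shadows.shape[1]):
            shadows[:, j] = rng.permutation(shadows[:, j])
        design = np.hstack([X[:, keep], shadows])
        rf = RandomForestClassifier(
            n_estimators=n_trees, random_state=int(rng.integers(2**31)), n_jobs=1
        )
        rf.fit(design, y)
        imp = rf.feature_importances_
        shadow_max = imp[len(keep):].max()
        real_imp = dict(zip(keep, imp[: len(keep)]))
        hits[tentative] += np.array([real_imp[f] > shadow_max for f in tentative])
        trials += 1

        # Bonferroni over the features still under test (the reference
        # Boruta's multiplicity adjustment); without it ~p_threshold * p
        # null features get falsely confirmed per run
        n_test = tentative.size
        for f in tentative:
            pv = min(binomtest(int(hits[f]), trials, 0.5).pvalue * n_test, 1.0)
            if pv < p_threshold:
                status[f] = CONFIRMED if hits[f] > trials / 2 else REJECTED

    selected = sorted(np.where(status == CONFIRMED)[0].tolist())
    return {"decisions": dict(enumerate(status)), "selected": selected, "n_iter": trials}


def l1_logistic_select(
    X, y, inner_cv: int = 5, seed: int | None = None, n_penalties: int = 20
) -> list[int]:
    """LASSO-logistic selection at the one-standard-error penalty.

    Inner stratified CV profiles the binomial deviance over a log-spaced
    penalty path; the strongest penalty whose mean deviance lies within
    one standard error of the minimum wins (the sparse, stability-minded
    convention — the deviance minimum itself admits a stable fringe of
    noise features). Returns indices with nonzero coefficients at that
    penalty. Features are standardized within the call; constant columns
    are dropped with a log entry."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    _check_xy(X, y)
    sd = X.std(axis=0)
    keep = np.where(sd > 0)[0]
    if keep.size < X.shape[1]:
        logger.info("l1_logistic_select: dropping %d constant feature(s)", X.shape[1] - keep.size)
    if keep.size == 0:
        return []
    Xs = StandardScaler().fit_transform(X[:, keep])
    yb = (y == np.unique(y)[1]).astype(float)
    n = len(yb)
    # penalty path relative to the smallest all-zero penalty, spanning two
    # decades when n < p (the reference lasso implementation's convention);
    # unrestricted deviance minimization on near-separable data otherwise
    # drifts into arbitrarily weak penalties
    lam_max = np.abs(Xs.T @ (yb - yb.mean())).max() / n
    ratio = 0.01 if n < Xs.shape[1] else 1e-4
    lams = np.exp(np.linspace(np.log(lam_max), np.log(ratio * lam_max), n_penalties))
    Cs = 1.0 / (n * lams)
    kw = dict(
        l1_ratio=1.0,
        solver="liblinear",
        max_iter=5000,
        random_state=seed,
        intercept_scaling=100.0,  # liblinear penalizes the intercept; damp it
    )
    cv = StratifiedKFold(n_splits=inner_cv, shuffle=True, random_state=seed)
    splits = list(cv.split(Xs, y))
    dev = np.zeros((len(Cs), len(splits)))
    for ci, C in enumerate(Cs):
        for si, (tr, va) in enumerate(splits):
            clf = LogisticRegression(C=C, **kw)
            clf.fit(Xs[tr], y[tr])
            p = np.clip(clf.predict_proba(Xs[va])[:, 1], 1e-12, 1 - 1e-12)
            dev[ci, si] = -2.0 * np.mean(yb[va] * np.log(p) + (1 - yb[va]) * np.log(1 - p))
    mean_dev = dev.mean(axis=1)
    se = dev.std(axis=1, ddof=1) / np.sqrt(len(splits))
    best = int(np.argmin(mean_dev))
    within = np.where(mean_dev <= mean_dev[best] + se[best])[0]
    chosen = Cs[int(within.min())]  # smallest C = strongest penalty
    final = LogisticRegression(C=chosen, **kw)
    final.fit(Xs, y)
    nz = np.where(np.abs(final.coef_.ravel()) > 0)[0]
    return sorted(keep[nz].tolist())


def _svm_weights(X: np.ndarray, y: np.ndarray, seed) -> np.ndarray:
    clf = make_pipeline(
        StandardScaler(),
        LinearSVC(C=1.0, dual=False, max_iter=10000, random_state=seed),
    )
    clf.fit(X, y)
    w = clf[-1].coef_.ravel()
    if not np.all(np.isfinite(w)):
        raise ValidationError("non-finite SVM weights")
    return np.abs(w)


def _rfe_path(
    X: np.ndarray, y: np.ndarray, sizes: list[int], step: float, seed
) -> dict[int, np.ndarray]:
    """Feature sets along the elimination path at each candidate size."""
    current = np.arange(X.shape[1])
    out: dict[int, np.ndarray] = {}
    if X.shape[1] in sizes:
        out[X.shape[1]] = current.copy()
    target_min = min(sizes)
    while current.size > target_min:
        w = _svm_weights(X[:, current], y, seed)
        nxt = max(int(np.floor(current.size * (1.0 - step))), target_min)
        between = [s for s in sizes if nxt < s < current.size]
        if between:
            nxt = max(between)
        order = np.argsort(-w, kind="stable")  # best first, index tie-break
        current = np.sort(current[order[:nxt]])
        if nxt in sizes:
            out[nxt] = current.copy()
    return out


def rfe_svm_select(
    X,
    y,
    subset_sizes=(5, 10, 20, 40),
    step: float = 0.5,
    inner_cv: int = 5,
    seed: int | None = None,
) -> list[int]:
    """Recursive feature elimination under a linear SVM.

    The lowest-|weight| fraction ``step`` is dropped per round until each
    candidate subset size is reached; the size with the best inner-CV
    balanced accuracy (tie -> smaller panel) wins, and the elimination is
    replayed on the full data down to that size.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    _check_xy(X, y)
    if not 0.0 < step < 1.0:
        raise ValidationError("step must be in (0, 1)")
    sizes = sorted({int(s) for s in subset_sizes if 1 <= s <= X.shape[1]})
    if not sizes:
        raise ValidationError("subset_sizes empty after clipping to [1, n_features]")
    if sizes == [X.shape[1]]:
        return list(range(X.shape[1]))

    cv = StratifiedKFold(n_splits=inner_cv, shuffle=True, random_state=seed)
    scores = {s: [] for s in sizes}
    for tr, va in cv.split(X, y):
        path = _rfe_path(X[tr], y[tr], sizes, step, seed)
        for s, feats in path.items():
            clf = make_pipeline(
                StandardScaler(), LinearSVC(C=1.0, dual=False, max_iter=10000, random_state=seed)
            )
            clf.fit(X[np.ix_(tr, feats)], y[tr])
            scores[s].append(balanced_accuracy_score(y[va], clf.predict(X[np.ix_(va, feats)])))
    mean_scores = {s: float(np.mean(v)) for s, v in scores.items()}
    best = min(sizes, key=lambda s: (-mean_scores[s], s))
    final = _rfe_path(X, y, [best], step, seed)[best]
    return sorted(final.tolist())


@dataclass
class SelectionRun:
    method: str
    repeat: int
    subsample_seed: int
    selected_features: list


@dataclass
class StablePanel:
    """Per-fold stability-selection outcome."""

    fold_index: int
    frequencies: pd.DataFrame  # feature x method retention fraction
    stable_features: list
    runs: list = field(default_factory=list, repr=False)

    def runs_table(self) -> pd.DataFrame:
        rows = [
            {"fold": self.fold_index, "method": r.method, "repeat": r.repeat, "feature": f}
            for r in self.runs
            for f in r.selected_features
        ]
        return pd.DataFrame(rows, columns=["fold", "method", "repeat", "feature"])


@dataclass
class ConsensusPanel:
    fold_counts: pd.Series  # feature -> number of folds whose stable panel has it
    consensus_features: list
    min_folds: int
    annotation: pd.DataFrame | None = None


def _stratified_subsample(y: np.ndarray, frac: float, rng: np.random.Generator) -> np.ndarray:
    idx = []
    for cls in np.unique(y):
        members = np.where(y == cls)[0]
        n_take = int(round(frac * members.size))
        if n_take < 2:
            raise ValidationError(f"subsample would leave < 2 samples in class {cls!r}")
        idx.append(rng.choice(members, size=n_take, replace=False))
    return np.sort(np.concatenate(idx))


def run_fold_selection(
    X_outer_train: pd.DataFrame,
    y,
    n_repeats: int = 10,
    subsample_frac: float = 0.8,
    retention_threshold: float = 0.7,
    seed: int | None = None,
    fold_index: int = 0,
    methods: tuple[str, ...] = METHODS,
    method_params: dict | None = None,
    pool_methods: bool = False,
) -> StablePanel:
    """Stability selection on one outer-training set.

    Draws ``n_repeats`` class-stratified ``subsample_frac`` subsamples
    (the same subsample feeds all three selectors in a repeat), records
    every selection, computes per-method retention frequencies and
    returns the stable panel: the union over methods of features with
    frequency >= ``retention_threshold``. With ``pool_methods=True`` a
    single frequency over all method-runs is thresholded instead.
    """
    if not isinstance(X_outer_train, pd.DataFrame):
        X_outer_train = pd.DataFrame(np.asarray(X_outer_train))
    y = np.asarray(y)
    _check_xy(X_outer_train.to_numpy(dtype=float), y)
    unknown = set(methods) - set(METHODS)
    if unknown:
        raise ValidationError(f"unknown selection methods: {sorted(unknown)}")
    params = {m: {} for m in METHODS}
    params.update(method_params or {})
    rng = np.random.default_rng(seed)
    features = X_outer_train.columns
    Xv = X_outer_train.to_numpy(dtype=float)

    runs: list[SelectionRun] = []
    for rep in range(1, n_repeats + 1):
        sub_seed = int(rng.integers(2**31))
        sub_rng = np.random.default_rng(sub_seed)
        rows = _stratified_subsample(y, subsample_frac, sub_rng)
        Xs, ys = Xv[rows], y[rows]
        for method in methods:
            m_seed = int(sub_rng.integers(2**31))
            if method == "boruta":
                sel = boruta_select(Xs, ys, seed=m_seed, **params["boruta"])["selected"]
            elif method == "l1_logistic":
                sel = l1_logistic_select(Xs, ys, seed=m_seed, **params["l1_logistic"])
            else:
                sel = rfe_svm_select(Xs, ys, seed=m_seed, **params["rfe_svm"])
            runs.append(
                SelectionRun(method, rep, sub_seed, [features[i] for i in sel])
            )

    return panel_from_runs(
        features,
        runs,
        n_repeats,
        retention_threshold,
        methods=methods,
        pool_methods=pool_methods,
        fold_index=fold_index,
    )


def panel_from_runs(
    features,
    runs: list[SelectionRun],
    n_repeats: int,
    retention_threshold: float = 0.7,
    methods: tuple[str, ...] = METHODS,
    pool_methods: bool = False,
    fold_index: int = 0,
) -> StablePanel:
    """Apply the retention-frequency rule to a log of selection runs.

    Per method, a feature's frequency is the fraction of repeats that
    selected it; the stable set is the union over methods of features at
    or above ``retention_threshold`` (or a single pooled frequency over
    all runs when ``pool_methods``)."""
    features = pd.Index(features)
    freq = pd.DataFrame(0.0, index=features, columns=list(methods))
    for r in runs:
        freq.loc[r.selected_features, r.method] += 1.0
    freq /= n_repeats

    eps = 1e-12
    if pool_methods:
        pooled = freq.mean(axis=1)
        stable_mask = pooled >= retention_threshold - eps
    else:
        stable_mask = (freq >= retention_threshold - eps).any(axis=1)
    stable = [f for f in features if stable_mask[f]]
    return StablePanel(fold_index=fold_index, frequencies=freq, stable_features=stable, runs=runs)


def build_consensus(
    per_fold_panels: list[StablePanel],
    min_folds: int = 3,
    feature_annotation: pd.DataFrame | None = None,
) -> ConsensusPanel:
    """Cross-fold consensus: features stable in >= ``min_folds`` folds.

    Features below the threshold stay in ``fold_counts`` with their
    counts, so near-misses (panels selected in only one or two folds)
    remain inspectable.
    """
    counts: dict = {}
    for panel in per_fold_panels:
        for f in panel.stable_features:
            counts[f] = counts.get(f, 0) + 1
    fold_counts = pd.Series(counts, dtype=int).sort_values(ascending=False)
    consensus = sorted(fold_counts.index[fold_counts >= min_folds].tolist())
    ann = feature_annotation.loc[consensus] if feature_annotation is not None else None
    return ConsensusPanel(
        fold_counts=fold_counts, consensus_features=consensus, min_folds=min_folds, annotation=ann
    )
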