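"""Candidate classifiers and their hyperparameter grids.

Four families: elastic-net logistic regression, linear SVM, radial SVM
and Gaussian naive Bayes. All expose predicted probabilities of the
Active class: logistic output for the elastic net and NB, Platt scaling
(fitted on training data only) for the SVMs. Decision threshold is
fixed at 0.5 everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist
from sklearn.linear_model import LogisticRegression
from sklearn.naive_bayes import GaussianNB
from sklearn.pipeline import Pipeline, make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from peptidia.containers import ValidationError

ELASTIC_NET = "elastic_net_logistic"
SVM_LINEAR = "svm_linear"
SVM_RADIAL = "svm_radial"
GAUSSIAN_NB = "gaussian_nb"
FAMILIES = (ELASTIC_NET, SVM_LINEAR, SVM_RADIAL, GAUSSIAN_NB)

#: sentinel: resolve against the training data's median pairwise distance
MEDIAN_GAMMA = "median_gamma"


@dataclass
class ModelSpec:
    """A classifier family plus its (nonempty) hyperparameter grid.

    Grid entries are plain dicts; for the radial SVM the ``gamma`` entry
    may be ``(MEDIAN_GAMMA, multiplier)`` and is resolved against the
    inner-training data at tuning time (median heuristic)."""

    family: str
    grid: list[dict] = field(default_factory=list)
    threshold: float = 0.5

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValidationError(f"unknown model family {self.family!r}")
        if not self.grid:
            self.grid = default_grid(self.family)
        if self.threshold != 0.5:
            raise ValidationError("decision threshold is fixed at 0.5")


def default_grid(family: str) -> list[dict]:
    if family == ELASTIC_NET:
        return [
            {"l1_ratio": a, "C": float(c)}
            for a in (0.0, 0.25, 0.5, 0.75, 1.0)
            for c in np.logspace(-2, 2, 20)
        ]
    if family == SVM_LINEAR:
        return [{"C": c} for c in (0.1, 1.0, 10.0, 100.0)]
    if family == SVM_RADIAL:
        return [
            {"C": c, "gamma": (MEDIAN_GAMMA, m)}
            for c in (0.1, 1.0, 10.0, 100.0)
            for m in (0.1, 1.0, 10.0)
        ]
    if family == GAUSSIAN_NB:
        return [{"var_smoothing": v} for v in (1e-9, 1e-7, 1e-5)]
    raise ValidationError(f"unknown model family {family!r}")


def default_specs() -> list[ModelSpec]:
    return [ModelSpec(f) for f in FAMILIES]


def median_heuristic_gamma(X: np.ndarray) -> float:
    """RBF width 1 / median squared pairwise Euclidean distance."""
    d2 = pdist(X, "sqeuclidean")
    med = np.median(d2[d2 > 0]) if np.any(d2 > 0) else 1.0
    return 1.0 / med


def resolve_hp(family: str, hp: dict, X_train: np.ndarray) -> dict:
    """Materialize data-dependent grid entries (radial gamma)."""
    hp = dict(hp)
    g = hp.get("gamma")
    if isinstance(g, tuple) and g[0] == MEDIAN_GAMMA:
        Xs = StandardScaler().fit_transform(np.asarray(X_train, dtype=float))
        hp["gamma"] = float(g[1] * median_heuristic_gamma(Xs))
    return hp


def make_estimator(family: str, hp: dict, seed: int | None = None) -> Pipeline | GaussianNB:
    """Seeded estimator with predict_proba, standardized inputs where the
    family is scale-sensitive."""
    if family == ELASTIC_NET:
        return make_pipeline(
            StandardScaler(),
            LogisticRegression(
                solver="saga",
                l1_ratio=hp["l1_ratio"],
                C=hp["C"],
                max_iter=20000,
                random_state=seed,
            ),
        )
    if family == SVM_LINEAR:
        return make_pipeline(
            StandardScaler(),
            SVC(kernel="linear", C=hp["C"], probability=True, random_state=seed),
        )
    if family == SVM_RADIAL:
        return make_pipeline(
            StandardScaler(),
            SVC(
                kernel="rbf",
                C=hp["C"],
                gamma=hp["gamma"],
                probability=True,
                random_state=seed,
            ),
        )
    if family == GAUSSIAN_NB:
        return GaussianNB(var_smoothing=hp["var_smoothing"])
    raise ValidationError(f"unknown model family {family!r}")


def linear_coefficients(fitted, family: str) -> tuple[np.ndarray, float] | None:
    """(coefficients, intercept) on the standardized scale for linear
    families; None for models without linear weights."""
    if family in (ELASTIC_NET, SVM_LINEAR):
        clf = fitted[-1]
        return clf.coef_.ravel().copy(), float(np.ravel(clf.intercept_)[0])
    return None
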