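"""Post-hoc interpretation of the consensus-panel model.

For a linear (penalized-logistic) model SHAP attributions are exact and
closed-form under feature independence: the contribution of feature j
for sample i is ``coef_j * (x_ij - reference_j)`` on the log-odds scale,
with the base value equal to the model's log-odds at the reference point
(feature means of the training data). Panel redundancy is profiled by
pairwise Pearson correlation with average-linkage clustering on the
``1 - r`` distance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, leaves_list
from scipy.spatial.distance import squareform

from peptidia.containers import ValidationError


@dataclass
class ShapMatrix:
    """Per-(sample, feature) log-odds contributions.

    Invariant: ``base_value + contributions.sum(axis=1)`` equals the
    model's log-odds output for every sample (to numerical precision)."""

    contributions: pd.DataFrame  # samples x features
    base_value: float
    reference: pd.Series

    def log_odds(self) -> pd.Series:
        return self.base_value + self.contributions.sum(axis=1)


def linear_shap(
    coefficients,
    intercept: float,
    X: pd.DataFrame,
    reference=None,
) -> ShapMatrix:
    """Exact additive attributions for a linear model on the log-odds scale.

    ``reference`` defaults to the feature means of ``X`` (the
    conventional linear-SHAP baseline)."""
    if not isinstance(X, pd.DataFrame):
        X = pd.DataFrame(np.asarray(X, dtype=float))
    coef = np.asarray(coefficients, dtype=float).ravel()
    if coef.size != X.shape[1]:
        raise ValidationError(f"{coef.size} coefficients for {X.shape[1]} features")
    if reference is None:
        ref = X.mean(axis=0)
    else:
        ref_arr = np.asarray(reference, dtype=float).ravel()
        if ref_arr.size != X.shape[1]:
            raise ValidationError("reference length does not match feature count")
        ref = pd.Series(ref_arr, index=X.columns)
    contrib = (X - ref) * coef
    base = float(intercept + coef @ ref.to_numpy())
    return ShapMatrix(contributions=contrib, base_value=base, reference=ref)


def panel_correlation(X: pd.DataFrame, panel=None) -> tuple[pd.DataFrame, list]:
    """Pearson correlation of the panel features plus a clustering order.

    Returns the correlation matrix and the average-linkage leaf order on
    the ``1 - r`` distance. Zero-variance features are an error."""
    if panel is not None:
        X = X[list(panel)]
    if not isinstance(X, pd.DataFrame):
        X = pd.DataFrame(np.asarray(X, dtype=float))
    sd = X.std(axis=0, ddof=1)
    dead = sd.index[sd == 0].tolist()
    if dead:
        raise ValidationError(f"zero-variance feature(s): {dead[:5]}")
    corr = X.corr(method="pearson")
    if corr.shape[0] < 3:
        order = list(corr.index)
    else:
        dist = squareform(np.clip(1.0 - corr.to_numpy(), 0.0, None), checks=False)
        order = [corr.index[i] for i in leaves_list(average(dist))]
    return corr, order


def within_between_protein_correlation(
    corr: pd.DataFrame, protein_of_feature: pd.Series
) -> tuple[float, float]:
    """Mean within- vs between-protein off-diagonal correlation."""
    prot = protein_of_feature.loc[corr.index].to_numpy()
    c = corr.to_numpy()
    iu = np.triu_indices_from(c, k=1)
    same = prot[iu[0]] == prot[iu[1]]
    within = float(c[iu][same].mean()) if same.any() else float("nan")
    between = float(c[iu][~same].mean()) if (~same).any() else float("nan")
    return within, between
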