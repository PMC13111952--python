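"""Preprocessing: raw intensities to an analysis-ready log2 matrix.

Fixed stage order (each stage is also callable on its own):

1. log2 transform
2. contaminant removal, then feature / sample missingness filters
3. quantile normalization (observed values only)
4. empirical-Bayes batch correction (:mod:`peptidia.combat`)
5. kNN imputation (protein-level matrix; residual peptide missingness
   before model fitting)

Two missingness thresholds are deliberately exposed: the loose 70%
sample filter and the strict 30% feature filter used to arrive at the
compact peptide modeling matrix. Defaults: ``feature_max_missing=0.30``,
``sample_max_missing=0.70``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.decomposition import PCA

from peptidia.combat import correct_batches
from peptidia.containers import PeptideMatrix, SampleAnnotation, ValidationError

__all__ = [
    "PreprocessConfig",
    "log2_transform",
    "filter_features_samples",
    "quantile_normalize",
    "knn_impute",
    "pca_scores",
    "collapse_to_proteins",
    "run_preprocess",
]


@dataclass
class PreprocessConfig:
    feature_max_missing: float = 0.30
    sample_max_missing: float = 0.70
    log_transform: bool = True
    normalize: bool = True
    batch_correct: bool = True
    impute: bool = True
    knn_k: int = 10

    def validate(self) -> None:
        for name in ("feature_max_missing", "sample_max_missing"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {v}")
        if self.knn_k < 1:
            raise ValidationError("knn_k must be >= 1")


def log2_transform(matrix: PeptideMatrix) -> PeptideMatrix:
    """log2 the observed entries; the missing mask is untouched."""
    if matrix.log2_scale:
        raise ValidationError("matrix is already on the log2 scale")
    x = matrix.intensities.to_numpy(dtype=float)
    bad = np.argwhere(~np.isnan(x) & (x <= 0))
    if bad.size:
        i, j = bad[0]
        raise ValidationError(
            f"non-positive intensity at feature {matrix.feature_ids[i]!r}, "
            f"sample {matrix.sample_ids[j]!r}: {x[i, j]}"
        )
    out = pd.DataFrame(
        np.log2(x), index=matrix.intensities.index, columns=matrix.intensities.columns
    )
    return matrix.with_values(out, log2_scale=True)


def filter_features_samples(matrix: PeptideMatrix, config: PreprocessConfig) -> PeptideMatrix:
    """Contaminants out first, then high-missing features, then
    high-missing samples (sample fractions computed on surviving
    features). Thresholds are strict: a feature is dropped only when its
    missing fraction *exceeds* the threshold."""
    config.validate()
    keep_feat = ~matrix.feature_annotation["is_contaminant"].to_numpy(dtype=bool)
    sub = matrix.subset(features=matrix.intensities.index[keep_feat])

    miss_f = sub.missing_mask.mean(axis=1)
    sub = sub.subset(features=miss_f.index[miss_f.to_numpy() <= config.feature_max_missing])
    if sub.n_features == 0:
        raise ValidationError("all features removed by contaminant/missingness filters")

    miss_s = sub.missing_mask.mean(axis=0)
    sub = sub.subset(samples=miss_s.index[miss_s.to_numpy() <= config.sample_max_missing])
    if sub.n_samples == 0:
        raise ValidationError("all samples removed by the missingness filter")
    return sub


def _reference_distribution(x: np.ndarray) -> np.ndarray:
    """Mean quantile function across columns, on a grid of length
    n_features. Complete equal-length columns reduce to the mean of the
    sorted columns."""
    m = x.shape[0]
    grid = np.linspace(0.0, 1.0, m)
    curves = []
    for j in range(x.shape[1]):
        col = np.sort(x[~np.isnan(x[:, j]), j])
        if col.size == 0:
            raise ValidationError(f"column {j} has no observed values")
        if col.size == 1:
            curves.append(np.full(m, col[0]))
        else:
            curves.append(np.interp(grid, np.linspace(0.0, 1.0, col.size), col))
    return np.mean(curves, axis=0)


def quantile_normalize(matrix: PeptideMatrix) -> PeptideMatrix:
    """Force every sample column onto the shared reference distribution.

    The reference is the across-column mean quantile function; each
    column's observed values are replaced by the reference evaluated at
    their rank positions (rank interpolation for incomplete columns).
    Ties receive the mean of the reference values at their tied ranks.
    Missing entries remain missing; within-column rank order of observed
    values is preserved.
    """
    if not matrix.log2_scale:
        raise ValidationError("quantile normalization expects log2-scale data")
    x = matrix.intensities.to_numpy(dtype=float)
    m = x.shape[0]
    ref = _reference_distribution(x)
    grid = np.linspace(0.0, 1.0, m)
    out = np.full_like(x, np.nan)
    for j in range(x.shape[1]):
        obs = ~np.isnan(x[:, j])
        col = x[obs, j]
        n_obs = col.size
        order_stats = (
            np.interp(np.linspace(0.0, 1.0, n_obs), grid, ref)
            if n_obs > 1
            else np.array([np.interp(0.5, grid, ref)])
        )
        pos = rankdata(col, method="ordinal") - 1
        base = order_stats[pos]
        # ties -> mean of the reference values at their tied ranks
        out[obs, j] = pd.Series(base).groupby(col).transform("mean").to_numpy()
    values = pd.DataFrame(out, index=matrix.intensities.index, columns=matrix.intensities.columns)
    return matrix.with_values(values)


def knn_impute(matrix: PeptideMatrix, k: int = 10) -> PeptideMatrix:
    """Feature-space k-nearest-neighbor imputation.

    For a missing cell (f, s) the k features nearest to f — Euclidean
    distance rescaled to the mutually observed samples, candidates
    restricted to features observed at s — are averaged. Features with no
    usable neighbor fall back to their own observed mean. Output has an
    empty missing mask.
    """
    if k < 1:
        raise ValidationError("k must be >= 1")
    x = matrix.intensities.to_numpy(dtype=float)
    obs = ~np.isnan(x)
    if obs.all():
        return matrix
    if (~obs).all(axis=1).any():
        bad = matrix.intensities.index[(~obs).all(axis=1)].tolist()
        raise ValidationError(f"feature(s) with no observed values cannot be imputed: {bad[:5]}")

    x0 = np.where(obs, x, 0.0)
    # pairwise sq Euclidean over mutual observations, scaled to full width
    overlap = obs.astype(float) @ obs.astype(float).T
    cross = x0 @ x0.T
    sq = (x0**2) @ obs.astype(float).T
    d2 = sq + sq.T - 2.0 * cross
    with np.errstate(divide="ignore", invalid="ignore"):
        d2 = np.where(overlap > 0, d2 / overlap, np.inf) * x.shape[1]
    np.fill_diagonal(d2, np.inf)

    out = x.copy()
    feat_means = np.nansum(x, axis=1) / obs.sum(axis=1)
    n_fallback = 0
    for f, s in zip(*np.where(~obs)):
        candidates = np.where(obs[:, s] & np.isfinite(d2[f]))[0]
        if candidates.size == 0:
            out[f, s] = feat_means[f]
            n_fallback += 1
            continue
        nearest = candidates[np.argsort(d2[f, candidates], kind="stable")[:k]]
        out[f, s] = x[nearest, s].mean()
    if n_fallback:
        warnings.warn(
            f"{n_fallback} cell(s) imputed by feature-mean fallback (no observed neighbor)",
            stacklevel=2,
        )
    values = pd.DataFrame(out, index=matrix.intensities.index, columns=matrix.intensities.columns)
    return matrix.with_values(values)


def pca_scores(matrix: PeptideMatrix, n_components: int = 2) -> pd.DataFrame:
    """Centered PCA sample scores for QC; attrs carry variance fractions."""
    x = matrix.intensities.to_numpy(dtype=float)
    if np.isnan(x).any():
        raise ValidationError("PCA requires a complete (imputed) matrix")
    n_max = min(matrix.n_features, matrix.n_samples)
    if n_components > n_max:
        raise ValidationError(f"n_components={n_components} exceeds min(features, samples)={n_max}")
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(x.T)
    df = pd.DataFrame(
        scores,
        index=matrix.intensities.columns,
        columns=[f"PC{i + 1}" for i in range(n_components)],
    )
    df.attrs["explained_variance_ratio"] = pca.explained_variance_ratio_.tolist()
    return df


def collapse_to_proteins(matrix: PeptideMatrix) -> PeptideMatrix:
    """Protein-level matrix: per-sample mean of each protein's observed
    peptide log2 intensities (missing where no peptide is observed)."""
    if not matrix.log2_scale:
        raise ValidationError("protein rollup expects log2-scale data")
    grouped = matrix.intensities.groupby(matrix.feature_annotation["protein_id"]).mean()
    ann = pd.DataFrame(
        {
            "protein_id": grouped.index,
            "sequence": "",
            "modification": "",
            "is_contaminant": False,
        },
        index=grouped.index,
    )
    return PeptideMatrix(intensities=grouped, feature_annotation=ann, log2_scale=True)


def run_preprocess(
    matrix: PeptideMatrix,
    annotation: SampleAnnotation,
    config: PreprocessConfig | None = None,
) -> PeptideMatrix:
    """The fixed pipeline order on one matrix."""
    config = config or PreprocessConfig()
    config.validate()
    if config.log_transform and not matrix.log2_scale:
        matrix = log2_transform(matrix)
    matrix = filter_features_samples(matrix, config)
    if config.normalize:
        matrix = quantile_normalize(matrix)
    if config.batch_correct:
        matrix = correct_batches(matrix, annotation.loc(matrix.sample_ids))
    if config.impute:
        matrix = knn_impute(matrix, k=config.knn_k)
    return matrix
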