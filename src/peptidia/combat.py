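"""Parametric empirical-Bayes batch correction (ComBat-style).

Location/scale adjustment for technical batch effects in a feature x
sample matrix: per feature the data are standardized against the
batch-weighted grand mean and pooled variance, per-batch location
(gamma) and scale (delta^2) estimates are shrunk toward batch-level
priors — Normal for gamma, inverse-gamma for delta^2, hyperparameters by
the method of moments — via iterated EB updates to convergence, and the
adjusted data are back-transformed. The design contains an intercept
only: no biological covariates are protected, so the correction must be
applied to technical batches uncorrelated with the biology.

Missing entries are tolerated: every moment is computed on observed
values and missing cells stay missing. A feature whose values are
entirely missing in some batch cannot be standardized there and is
passed through uncorrected (reported on the model).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from peptidia.containers import PeptideMatrix, SampleAnnotation, ValidationError, check_aligned


@dataclass
class BatchModel:
    """Fitted EB batch model for :func:`apply_batch_correction`.

    gamma_star / delta2_star are (feature x batch) shrunk location and
    scale parameters; ``grand_mean`` and ``pooled_var`` define the
    per-feature standardization. ``skipped_features`` were left
    uncorrected (a fully-missing batch).
    """

    batches: list
    batch_of_sample: pd.Series
    grand_mean: pd.Series
    pooled_var: pd.Series
    gamma_hat: pd.DataFrame
    delta2_hat: pd.DataFrame
    gamma_star: pd.DataFrame
    delta2_star: pd.DataFrame
    gamma_bar: pd.Series
    tau2_bar: pd.Series
    a_prior: pd.Series
    b_prior: pd.Series
    skipped_features: list = field(default_factory=list)
    identity: bool = False


def _aprior(delta_hat: np.ndarray) -> float:
    m, s2 = delta_hat.mean(), delta_hat.var(ddof=1)
    return (2.0 * s2 + m**2) / s2


def _bprior(delta_hat: np.ndarray) -> float:
    m, s2 = delta_hat.mean(), delta_hat.var(ddof=1)
    return (m * s2 + m**3) / s2


def _it_sol(
    s_data: np.ndarray,
    g_hat: np.ndarray,
    d_hat: np.ndarray,
    g_bar: float,
    t2: float,
    a: float,
    b: float,
    conv: float = 1e-4,
) -> tuple[np.ndarray, np.ndarray]:
    """Iterated EB update for one batch (features vectorized)."""
    n = np.sum(~np.isnan(s_data), axis=1).astype(float)
    g_old, d_old = g_hat.copy(), d_hat.copy()
    change = 1.0
    while change > conv:
        g_new = (t2 * n * g_hat + d_old * g_bar) / (t2 * n + d_old)
        sum2 = np.nansum((s_data - g_new[:, None]) ** 2, axis=1)
        d_new = (0.5 * sum2 + b) / (n / 2.0 + a - 1.0)
        # NB: the reference implementation divides by the signed previous
        # value, so negative-gamma entries never drive the max; replicated
        # verbatim to stay numerically interchangeable with it
        change = max(
            np.max(np.abs(g_new - g_old) / g_old),
            np.max(np.abs(d_new - d_old) / d_old),
        )
        g_old, d_old = g_new, d_new
    return g_old, d_old


def fit_batch_model(matrix: PeptideMatrix, annotation: SampleAnnotation) -> BatchModel:
    """Estimate per-(feature, batch) EB location/scale parameters.

    Requires >= 2 batches each with >= 2 samples; with a single batch an
    identity model is returned with a warning.
    """
    if not matrix.log2_scale:
        raise ValidationError("batch correction expects log2-scale data")
    check_aligned(matrix, annotation)
    batch = annotation.table.loc[matrix.sample_ids, "batch"]
    batches = sorted(batch.unique())
    counts = batch.value_counts()

    if len(batches) == 1:
        warnings.warn("single batch: batch correction is the identity", stacklevel=2)
        empty = pd.DataFrame(index=matrix.intensities.index, columns=batches, dtype=float)
        zeros = pd.Series(0.0, index=matrix.intensities.index)
        return BatchModel(
            batches=batches,
            batch_of_sample=batch,
            grand_mean=zeros,
            pooled_var=zeros + 1.0,
            gamma_hat=empty,
            delta2_hat=empty,
            gamma_star=empty,
            delta2_star=empty,
            gamma_bar=pd.Series(dtype=float),
            tau2_bar=pd.Series(dtype=float),
            a_prior=pd.Series(dtype=float),
            b_prior=pd.Series(dtype=float),
            identity=True,
        )
    if (counts < 2).any():
        bad = counts[counts < 2].index.tolist()
        raise ValidationError(f"batches of size 1 cannot be corrected: {bad}")

    x = matrix.intensities.to_numpy(dtype=float)
    feat_index = matrix.intensities.index
    masks = {b: (batch == b).to_numpy() for b in batches}

    # features with a fully-missing batch pass through uncorrected
    obs = ~np.isnan(x)
    ok = np.ones(x.shape[0], dtype=bool)
    for b in batches:
        ok &= obs[:, masks[b]].sum(axis=1) >= 1
    skipped = feat_index[~ok].tolist()
    if skipped:
        warnings.warn(
            f"{len(skipped)} feature(s) have a fully-missing batch and are passed "
            "through uncorrected",
            stacklevel=2,
        )
    xf = x[ok]

    n_total = x.shape[1]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        batch_means = np.column_stack([np.nanmean(xf[:, masks[b]], axis=1) for b in batches])
    n_b = np.array([masks[b].sum() for b in batches], dtype=float)
    grand = batch_means @ (n_b / n_total)
    # pooled variance around the fitted batch means, denominator = n
    fitted = np.zeros_like(xf)
    for j, b in enumerate(batches):
        fitted[:, masks[b]] = batch_means[:, [j]]
    resid = xf - fitted
    pooled = np.nansum(resid**2, axis=1) / n_total
    pooled = np.where(pooled <= 0, np.finfo(float).tiny, pooled)

    s_data = (xf - grand[:, None]) / np.sqrt(pooled)[:, None]

    gamma_hat = np.empty((xf.shape[0], len(batches)))
    delta2_hat = np.empty_like(gamma_hat)
    gamma_star = np.empty_like(gamma_hat)
    delta2_star = np.empty_like(gamma_hat)
    gamma_bar, tau2_bar, a_pr, b_pr = [], [], [], []
    for j, b in enumerate(batches):
        sb = s_data[:, masks[b]]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            g = np.nanmean(sb, axis=1)
            d = np.nanvar(sb, axis=1, ddof=1)
        d = np.where(np.isnan(d) | (d <= 0), 1.0, d)  # single observed value in batch
        gbar, t2 = g.mean(), g.var(ddof=1)
        a, bp = _aprior(d), _bprior(d)
        gs, ds = _it_sol(sb, g, d, gbar, t2, a, bp)
        gamma_hat[:, j], delta2_hat[:, j] = g, d
        gamma_star[:, j], delta2_star[:, j] = gs, ds
        gamma_bar.append(gbar)
        tau2_bar.append(t2)
        a_pr.append(a)
        b_pr.append(bp)

    fi = feat_index[ok]
    return BatchModel(
        batches=batches,
        batch_of_sample=batch,
        grand_mean=pd.Series(grand, index=fi),
        pooled_var=pd.Series(pooled, index=fi),
        gamma_hat=pd.DataFrame(gamma_hat, index=fi, columns=batches),
        delta2_hat=pd.DataFrame(delta2_hat, index=fi, columns=batches),
        gamma_star=pd.DataFrame(gamma_star, index=fi, columns=batches),
        delta2_star=pd.DataFrame(delta2_star, index=fi, columns=batches),
        gamma_bar=pd.Series(gamma_bar, index=batches),
        tau2_bar=pd.Series(tau2_bar, index=batches),
        a_prior=pd.Series(a_pr, index=batches),
        b_prior=pd.Series(b_pr, index=batches),
        skipped_features=skipped,
    )


def apply_batch_correction(matrix: PeptideMatrix, model: BatchModel) -> PeptideMatrix:
    """Back-transform with the shrunk batch parameters.

    ``y* = sqrt(pooled_var / delta2*) * (z - gamma*) * ... + grand_mean``
    applied per batch on the standardized scale; skipped features and
    missing cells are returned unchanged.
    """
    if model.identity:
        return matrix
    out = matrix.intensities.copy()
    fi = model.grand_mean.index
    x = out.loc[fi].to_numpy(dtype=float)
    grand = model.grand_mean.to_numpy()
    pooled = model.pooled_var.to_numpy()
    s_data = (x - grand[:, None]) / np.sqrt(pooled)[:, None]
    batch = model.batch_of_sample.loc[out.columns]
    for j, b in enumerate(model.batches):
        cols = (batch == b).to_numpy()
        gs = model.gamma_star.iloc[:, j].to_numpy()[:, None]
        ds = model.delta2_star.iloc[:, j].to_numpy()[:, None]
        s_data[:, cols] = (s_data[:, cols] - gs) / np.sqrt(ds)
    adj = s_data * np.sqrt(pooled)[:, None] + grand[:, None]
    out.loc[fi] = adj
    return matrix.with_values(out)


def correct_batches(matrix: PeptideMatrix, annotation: SampleAnnotation) -> PeptideMatrix:
    """Fit + apply in one call."""
    return apply_batch_correction(matrix, fit_batch_model(matrix, annotation))
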