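"""Protein-level differential abundance: Welch tests, BH, volcano.

Active minus Remission on the log2 scale; a protein is called up
(respectively down) when the BH-adjusted p-value is strictly below
``alpha`` and the log2 fold change is strictly above ``lfc_threshold``
(strictly below its negative). Plain Welch tests — no moderated variance
shrinkage.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from peptidia.containers import (
    ACTIVE,
    REMISSION,
    PeptideMatrix,
    SampleAnnotation,
    ValidationError,
    check_aligned,
)

UP, DOWN, NS = "up", "down", "ns"


def welch_test(values_active, values_remission) -> tuple[float, float, float]:
    """Welch's unequal-variance t-test plus the log2 fold change.

    Returns ``(t, p, log2fc)`` with ``log2fc = mean(active) -
    mean(remission)`` and a two-sided p-value on Welch–Satterthwaite
    degrees of freedom. Each group needs >= 2 observations.
    """
    a = np.asarray(values_active, dtype=float)
    r = np.asarray(values_remission, dtype=float)
    a, r = a[~np.isnan(a)], r[~np.isnan(r)]
    if a.size < 2 or r.size < 2:
        raise ValidationError(
            f"Welch test needs >= 2 observed values per group (got {a.size} and {r.size})"
        )
    res = stats.ttest_ind(a, r, equal_var=False)
    return float(res.statistic), float(res.pvalue), float(a.mean() - r.mean())


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (order-preserving)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def volcano_classify(
    matrix: PeptideMatrix,
    annotation: SampleAnnotation,
    alpha: float = 0.05,
    lfc_threshold: float = 0.6,
) -> pd.DataFrame:
    """Per-protein Welch + BH + volcano categories.

    Returns a DataFrame indexed by feature id with columns ``log2fc``,
    ``p_value``, ``adj_p``, ``category`` and attrs ``n_up`` / ``n_down``.
    Expects the complete (imputed) protein-level matrix.
    """
    check_aligned(matrix, annotation)
    act = annotation.table.loc[matrix.sample_ids, "activity"]
    for cls in (ACTIVE, REMISSION):
        if (act == cls).sum() < 2:
            raise ValidationError(f"need >= 2 samples of class {cls}")
    x = matrix.intensities
    a_cols = x.columns[(act == ACTIVE).to_numpy()]
    r_cols = x.columns[(act == REMISSION).to_numpy()]

    rows = []
    for feat in x.index:
        t, p, lfc = welch_test(x.loc[feat, a_cols], x.loc[feat, r_cols])
        rows.append((feat, t, p, lfc))
    res = pd.DataFrame(rows, columns=["feature", "t", "p_value", "log2fc"]).set_index("feature")
    res["adj_p"] = bh_adjust(res["p_value"].to_numpy())
    sig = res["adj_p"] < alpha
    res["category"] = np.select(
        [sig & (res["log2fc"] > lfc_threshold), sig & (res["log2fc"] < -lfc_threshold)],
        [UP, DOWN],
        default=NS,
    )
    res.attrs["n_up"] = int((res["category"] == UP).sum())
    res.attrs["n_down"] = int((res["category"] == DOWN).sum())
    return res[["log2fc", "p_value", "adj_p", "category"]]
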