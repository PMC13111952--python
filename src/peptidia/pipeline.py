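"""Top-level pipeline: simulate/ingest -> preprocess -> differential ->
nested CV -> interpretation, with every stage's inputs and outputs
persisted under the run directory. One integer seed drives everything;
identical config + seed gives byte-identical artifacts.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from peptidia import io
from peptidia.cohort import generate_cohort
from peptidia.config import PipelineConfig, dump_config
from peptidia.containers import PeptideMatrix, SampleAnnotation
from peptidia.differential import volcano_classify
from peptidia.interpret import linear_shap, panel_correlation
from peptidia.models import ELASTIC_NET, ModelSpec, linear_coefficients, make_estimator
from peptidia.nested import NestedResult, run_nested_cv, tune_inner
from peptidia.preprocess import collapse_to_proteins, knn_impute, pca_scores, run_preprocess

logger = logging.getLogger(__name__)

FLOAT_FMT = "%.17g"


def _write(df: pd.DataFrame, path: Path, **kw) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, float_format=FLOAT_FMT, **kw)


def _ingest(cfg: PipelineConfig) -> tuple[PeptideMatrix, SampleAnnotation]:
    if cfg.input.matrix is None:
        cohort_cfg = dataclasses.replace(cfg.cohort, seed=cfg.seed)
        return generate_cohort(cohort_cfg)
    matrix = io.read_matrix(
        cfg.input.matrix,
        dialect=cfg.input.dialect,
        annotation_path=cfg.input.features,
        log2_scale=cfg.input.log2_scale,
    )
    annotation = io.read_samples(cfg.input.samples)
    return matrix, annotation


def run_pipeline(cfg: PipelineConfig, out_dir=None) -> NestedResult:
    """Execute the full workflow and persist artifacts.

    Stages: (1) simulate or ingest the peptide matrix and sample
    metadata; (2) preprocess the peptide modeling matrix and, via
    protein rollup, the protein matrix; (3) protein-level volcano;
    (4) nested cross-validation with stability selection on peptides;
    (5) post-hoc consensus-model interpretation (exact linear SHAP,
    panel correlation). Any stage failure aborts with the stage name;
    artifacts written so far stay on disk."""
    out = Path(out_dir if out_dir is not None else cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    dump_config(cfg, out / "config_resolved.yaml")
    rng = np.random.default_rng(cfg.seed)
    stage = "ingest"
    try:
        matrix, annotation = _ingest(cfg)
        io.write_matrix(matrix, out / "raw_matrix.tsv")
        io.write_feature_annotation(matrix, out / "features.csv")
        io.write_samples(annotation, out / "samples.csv")

        stage = "preprocess"
        peptide = run_preprocess(matrix, annotation, cfg.preprocess)
        io.write_matrix(peptide, out / "peptide_matrix_preprocessed.tsv")
        if not peptide.missing_mask.to_numpy().any():
            qc = pca_scores(peptide, n_components=2)
            qc["batch"] = annotation.table.loc[qc.index, "batch"]
            qc["activity"] = annotation.table.loc[qc.index, "activity"]
            _write(qc, out / "qc_pca.csv")

        stage = "differential"
        pre_impute_cfg = dataclasses.replace(cfg.preprocess, impute=False)
        protein = collapse_to_proteins(run_preprocess(matrix, annotation, pre_impute_cfg))
        protein = knn_impute(protein, k=cfg.preprocess.knn_k)
        annotation_used = annotation.loc(protein.sample_ids)
        volcano = volcano_classify(protein, annotation_used)
        _write(volcano, out / "volcano.csv")
        io.write_matrix(protein, out / "protein_matrix_imputed.tsv")

        stage = "nested_cv"
        result = run_nested_cv(
            peptide,
            annotation.loc(peptide.sample_ids),
            specs=cfg.model_specs(),
            selection=cfg.selection,
            k_outer=cfg.evaluation.k_outer,
            k_inner=cfg.evaluation.k_inner,
            seed=int(rng.integers(2**31)),
        )
        _persist_nested(result, out)

        stage = "interpret"
        if cfg.interpret.enabled and result.consensus.consensus_features:
            _interpret(peptide, annotation, result, out, seed=int(rng.integers(2**31)))
        return result
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc


def _persist_nested(result: NestedResult, out: Path) -> None:
    plan = pd.DataFrame(
        {"fold": result.fold_plan.assignments, "cell": result.fold_plan.cells}
    )
    plan.index.name = "sample_id"
    _write(plan, out / "fold_plan.csv")

    runs = pd.concat([p.runs_table() for p in result.panels], ignore_index=True)
    _write(runs, out / "selection_runs.csv", index=False)
    freqs = pd.concat(
        {p.fold_index: p.frequencies for p in result.panels}, names=["fold", "feature"]
    )
    _write(freqs, out / "selection_frequencies.csv")

    cons = result.consensus.fold_counts.rename("fold_count").to_frame()
    cons.index.name = "feature"
    cons["in_consensus"] = cons.index.isin(result.consensus.consensus_features)
    if result.consensus.annotation is not None:
        cons = cons.join(result.consensus.annotation, how="left")
    _write(cons, out / "consensus_panel.csv")

    fit_log = pd.DataFrame(
        [
            {
                "fold": r.fold,
                "model": r.family,
                "panel_size": len(r.panel),
                "inner_auc": r.inner_auc,
                **{f"hp_{k}": v for k, v in r.chosen_hp.items()},
            }
            for r in result.models
        ]
    )
    _write(fit_log, out / "fit_log.csv", index=False)

    for family, report in result.reports.items():
        d = out / "models" / family
        _write(report.predictions, d / "predictions.csv", index=False)
        _write(report.per_fold, d / "metrics_per_fold.csv")
        _write(report.summary, d / "metrics_summary.csv")
        _write(report.pooled["roc"], d / "roc_points.csv", index=False)
        _write(report.pooled["pr"], d / "pr_points.csv", index=False)
        gray = pd.DataFrame(
            [{"n": report.gray_zone["n"], **report.gray_zone.get("metrics", {})}]
        )
        _write(gray, d / "gray_zone_metrics.csv", index=False)
        pooled = pd.DataFrame(
            [{"roc_auc": report.pooled["roc_auc"], "pr_auc": report.pooled["pr_auc"]}]
        )
        _write(pooled, d / "pooled_auc.csv", index=False)


def _interpret(
    peptide: PeptideMatrix,
    annotation: SampleAnnotation,
    result: NestedResult,
    out: Path,
    seed: int,
) -> None:
    """Post-hoc model on the full cohort restricted to the consensus
    panel (clearly a descriptive refit, not an unbiased estimate)."""
    panel = result.consensus.consensus_features
    X = peptide.intensities.T[panel]
    y = annotation.loc(X.index).y()
    spec = ModelSpec(ELASTIC_NET)
    hp, _ = tune_inner(X.to_numpy(), y, spec, seed=seed)
    est = make_estimator(ELASTIC_NET, hp, seed=seed)
    est.fit(X.to_numpy(), y)
    coef, intercept = linear_coefficients(est, ELASTIC_NET)
    # attributions on the standardized scale the model was fit on
    scaler = est[0]
    Xs = pd.DataFrame(scaler.transform(X.to_numpy()), index=X.index, columns=X.columns)
    shap = linear_shap(coef, intercept, Xs)
    _write(shap.contributions, out / "shap_contributions.csv")
    pd.DataFrame([{"base_value": shap.base_value}]).to_csv(
        out / "shap_base.csv", index=False, float_format=FLOAT_FMT
    )
    corr, order = panel_correlation(X)
    _write(corr, out / "panel_correlation.csv")
    pd.Series(order, name="feature").to_csv(out / "panel_cluster_order.csv", index=False)
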