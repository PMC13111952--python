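"""Readers and writers for the matrix and metadata dialects.

Canonical matrix format is wide TSV: feature ids in the first column
(``feature_id``), one column per sample, empty cell = missing. A long
CSV dialect (``feature,sample,intensity``) is accepted for DIA-NN-style
exports. Feature annotation and sample metadata travel as CSV.
Write -> read round-trips are exact (values serialized with repr
precision).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from peptidia.containers import FEATURE_COLUMNS, PeptideMatrix, SampleAnnotation

WIDE_TSV = "wide_tsv"
LONG_CSV = "long_csv"


class ParseError(ValueError):
    pass


def _default_annotation(feature_ids: pd.Index) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "protein_id": feature_ids,
            "sequence": "",
            "modification": "",
            "is_contaminant": False,
        },
        index=feature_ids,
    )


def read_matrix(
    path,
    dialect: str = WIDE_TSV,
    annotation_path=None,
    log2_scale: bool = True,
) -> PeptideMatrix:
    """Read an intensity matrix; missing cells become the mask."""
    path = Path(path)
    if path.stat().st_size == 0:
        raise ParseError(f"{path}: empty file")
    if dialect == WIDE_TSV:
        try:
            df = pd.read_csv(path, sep="\t", index_col=0)
        except Exception as exc:  # ragged rows, non-numeric header cells
            raise ParseError(f"{path}: {exc}") from exc
        if df.index.has_duplicates:
            dupes = df.index[df.index.duplicated()].unique().tolist()
            raise ParseError(f"{path}: duplicate feature ids {dupes[:5]}")
        if df.columns.has_duplicates:
            raise ParseError(f"{path}: duplicate sample ids")
        non_numeric = df.columns[
            [not np.issubdtype(t, np.number) for t in df.dtypes]
        ].tolist()
        if non_numeric:
            for col in non_numeric:
                bad = df[pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()]
                if len(bad):
                    # +2: header line plus 1-based counting
                    line = int(df.index.get_loc(bad.index[0])) + 2
                    raise ParseError(
                        f"{path}: non-numeric cell in column {col!r} near line {line}"
                    )
            df = df.apply(pd.to_numeric)
    elif dialect == LONG_CSV:
        try:
            long = pd.read_csv(path)
        except Exception as exc:
            raise ParseError(f"{path}: {exc}") from exc
        required = {"feature", "sample", "intensity"}
        if not required <= set(long.columns):
            raise ParseError(f"{path}: long CSV needs columns {sorted(required)}")
        if long.duplicated(["feature", "sample"]).any():
            raise ParseError(f"{path}: duplicate (feature, sample) pairs")
        vals = pd.to_numeric(long["intensity"], errors="coerce")
        bad = long[vals.isna() & long["intensity"].notna()]
        if len(bad):
            raise ParseError(f"{path}: non-numeric intensity at line {int(bad.index[0]) + 2}")
        long["intensity"] = vals
        df = long.pivot(index="feature", columns="sample", values="intensity")
        df.index.name = "feature_id"
    else:
        raise ParseError(f"unknown dialect {dialect!r}")

    df = df.astype(float)
    if annotation_path is not None:
        ann = pd.read_csv(annotation_path, index_col=0)
        for col in FEATURE_COLUMNS:
            if col not in ann.columns:
                ann[col] = False if col == "is_contaminant" else ""
        ann = ann.loc[df.index, list(FEATURE_COLUMNS)]
        ann["is_contaminant"] = ann["is_contaminant"].astype(bool)
        ann[["sequence", "modification"]] = ann[["sequence", "modification"]].fillna("")
    else:
        ann = _default_annotation(df.index)
    return PeptideMatrix(intensities=df, feature_annotation=ann, log2_scale=log2_scale)


def write_matrix(matrix: PeptideMatrix, path, dialect: str = WIDE_TSV) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = matrix.intensities.copy()
    df.index.name = "feature_id"
    if dialect == WIDE_TSV:
        df.to_csv(path, sep="\t", float_format="%.17g", na_rep="")
    elif dialect == LONG_CSV:
        long = (
            df.stack(future_stack=True)
            .dropna()
            .rename("intensity")
            .reset_index()
            .rename(columns={"feature_id": "feature", "level_1": "sample"})
        )
        long.columns = ["feature", "sample", "intensity"]
        long.to_csv(path, index=False, float_format="%.17g")
    else:
        raise ParseError(f"unknown dialect {dialect!r}")


def write_feature_annotation(matrix: PeptideMatrix, path) -> None:
    ann = matrix.feature_annotation.copy()
    ann.index.name = "feature_id"
    ann.to_csv(path)


def read_samples(path) -> SampleAnnotation:
    df = pd.read_csv(path, index_col=0)
    return SampleAnnotation(df[["activity", "batch", "fc_value"]])


def write_samples(annotation: SampleAnnotation, path) -> None:
    t = annotation.table.copy()
    t.index.name = "sample_id"
    t.to_csv(path, float_format="%.17g")
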