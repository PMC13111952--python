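"""Core in-memory containers shared by every pipeline stage.

Intensities live in a pandas DataFrame with features (peptides or proteins)
as rows and samples as columns; ``NaN`` is the missing-value sentinel, so
the missing mask is always derivable and no numeric placeholder can leak
into downstream statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

GRAY_ZONE_LOW = 100.0  # µg/g fecal calprotectin
GRAY_ZONE_HIGH = 250.0

ACTIVE = "Active"
REMISSION = "Remission"

FEATURE_COLUMNS = ("protein_id", "sequence", "modification", "is_contaminant")


class ValidationError(ValueError):
    """Raised when a container or configuration violates its invariants."""


@dataclass
class PeptideMatrix:
    """Feature x sample intensity grid with annotation and a scale flag.

    Parameters
    ----------
    intensities
        DataFrame, features as rows and samples as columns. ``NaN`` marks
        missing cells.
    feature_annotation
        DataFrame indexed like ``intensities`` with columns
        ``protein_id``, ``sequence``, ``modification``,
        ``is_contaminant``.
    log2_scale
        True once values are log2-transformed. Statistical stages refuse
        raw-scale input.
    """

    intensities: pd.DataFrame
    feature_annotation: pd.DataFrame
    log2_scale: bool = False

    def __post_init__(self) -> None:
        self.intensities = self.intensities.rename_axis(index="feature_id", columns="sample_id")
        self.feature_annotation = self.feature_annotation.rename_axis(index="feature_id")
        idx = self.intensities.index
        if idx.has_duplicates:
            dupes = idx[idx.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate feature ids: {dupes[:5]}")
        if self.intensities.columns.has_duplicates:
            raise ValidationError("duplicate sample ids in intensity matrix")
        if not idx.equals(self.feature_annotation.index):
            raise ValidationError("feature annotation index does not match intensity rows")
        missing_cols = set(FEATURE_COLUMNS) - set(self.feature_annotation.columns)
        if missing_cols:
            raise ValidationError(f"feature annotation lacks columns: {sorted(missing_cols)}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.intensities.columns)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.intensities.index)

    @property
    def missing_mask(self) -> pd.DataFrame:
        """Boolean grid, True where the value is missing."""
        return self.intensities.isna()

    @property
    def n_features(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_samples(self) -> int:
        return self.intensities.shape[1]

    def with_values(self, values: pd.DataFrame, *, log2_scale: bool | None = None) -> "PeptideMatrix":
        """Return a copy carrying ``values`` (same index/columns required)."""
        if not values.index.equals(self.intensities.index) or not values.columns.equals(
            self.intensities.columns
        ):
            raise ValidationError("replacement values must share index and columns")
        return replace(
            self,
            intensities=values,
            log2_scale=self.log2_scale if log2_scale is None else log2_scale,
        )

    def subset(self, features=None, samples=None) -> "PeptideMatrix":
        """Row/column subset preserving annotation alignment."""
        feats = self.intensities.index if features is None else pd.Index(features)
        samps = self.intensities.columns if samples is None else pd.Index(samples)
        return replace(
            self,
            intensities=self.intensities.loc[feats, samps],
            feature_annotation=self.feature_annotation.loc[feats],
        )

    def equals(self, other: "PeptideMatrix") -> bool:
        return (
            self.log2_scale == other.log2_scale
            and self.intensities.equals(other.intensities)
            and self.feature_annotation.equals(other.feature_annotation)
        )


def is_gray_zone(fc_value) -> np.ndarray | bool:
    """Closed-interval gray-zone test on fecal calprotectin (µg/g)."""
    v = np.asarray(fc_value, dtype=float)
    out = (v >= GRAY_ZONE_LOW) & (v <= GRAY_ZONE_HIGH)
    return bool(out) if out.ndim == 0 else out


@dataclass
class SampleAnnotation:
    """Per-sample class labels, batch, calprotectin and gray-zone flag.

    ``table`` is indexed by sample id with columns ``activity``
    (Active/Remission), ``batch``, ``fc_value`` (µg/g) and the derived
    boolean ``gray_zone``.
    """

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        t = self.table
        if t.index.has_duplicates:
            raise ValidationError("duplicate sample ids in annotation")
        required = {"activity", "batch", "fc_value"}
        if not required <= set(t.columns):
            raise ValidationError(f"annotation lacks columns: {sorted(required - set(t.columns))}")
        bad = set(t["activity"].unique()) - {ACTIVE, REMISSION}
        if bad:
            raise ValidationError(f"unknown activity labels: {sorted(bad)}")
        if (t["fc_value"] < 0).any():
            raise ValidationError("negative fecal calprotectin value")
        derived = is_gray_zone(t["fc_value"].to_numpy())
        if "gray_zone" in t.columns:
            if not np.array_equal(t["gray_zone"].to_numpy(dtype=bool), derived):
                raise ValidationError("gray_zone flag inconsistent with fc_value interval test")
        else:
            self.table = t.assign(gray_zone=derived)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def activity(self) -> pd.Series:
        return self.table["activity"]

    @property
    def batch(self) -> pd.Series:
        return self.table["batch"]

    @property
    def gray_zone(self) -> pd.Series:
        return self.table["gray_zone"]

    def y(self, samples=None) -> np.ndarray:
        """Binary labels, 1 = Active (the positive class throughout)."""
        act = self.table["activity"] if samples is None else self.table.loc[samples, "activity"]
        return (act == ACTIVE).to_numpy(dtype=int)

    def strat_cells(self) -> pd.Series:
        """Joint stratification cell: activity x gray-zone status."""
        gz = np.where(self.table["gray_zone"], "Gray", "NonGray")
        return pd.Series(
            self.table["activity"].astype(str) + "/" + gz, index=self.table.index, name="cell"
        )

    def loc(self, samples) -> "SampleAnnotation":
        return SampleAnnotation(self.table.loc[samples])


def check_aligned(matrix: PeptideMatrix, annotation: SampleAnnotation) -> None:
    """Every matrix sample must appear exactly once in the annotation."""
    missing = [s for s in matrix.sample_ids if s not in annotation.table.index]
    if missing:
        raise ValidationError(f"samples missing from annotation: {missing[:5]}")
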