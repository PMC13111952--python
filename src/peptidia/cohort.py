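"""Synthetic stool-peptidomics cohort generator.

Emulates the statistical structure a DIA peptide-intensity study hands to
the analysis: a cohort with fixed Active/Remission and calprotectin
gray-zone composition acquired in several LC–MS batches, peptides nested
in parent proteins through a shared per-sample protein latent (so peptides
of one protein co-vary), additive + multiplicative batch shifts on the
log2 scale, and intensity-dependent (MNAR) plus completely-random (MCAR)
dropout. Generation starts at the quantified intensity matrix; no spectra
or retention times are simulated.

All randomness flows from the single integer ``seed`` in the config
through one named generator — identical configs give bit-identical
cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from peptidia.containers import (
    ACTIVE,
    GRAY_ZONE_HIGH,
    GRAY_ZONE_LOW,
    REMISSION,
    PeptideMatrix,
    SampleAnnotation,
    ValidationError,
)

AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

#: Consensus-panel effect sizes: (protein id, Active-vs-Remission log2FC,
#: number of peptides). The log2FC is the mean of the panel peptides
#: reported for that protein (peptide-level values 1.82–2.54).
DEFAULT_INFORMATIVE: tuple[tuple[str, float, int], ...] = (
    ("A1AG1", 1.82, 1),
    ("S10A8", 2.29, 2),
    ("S10A9", 2.05, 2),
    ("TRFL", 2.37, 2),
    ("PRTN3", 2.115, 2),
)


class ConfigError(ValidationError):
    """Infeasible cohort configuration."""


@dataclass
class CohortConfig:
    """Parameters of the simulated cohort.

    Defaults reproduce the study composition: 174 samples (66 Active /
    108 Remission), 34 gray-zone samples (21 Active / 13 Remission),
    four acquisition batches, 175 proteins yielding roughly 670-700
    peptides, and five informative proteins carrying nine panel peptides
    with log2 fold changes of about 1.8-2.5.
    """

    n_samples: int = 174
    n_active: int = 66
    n_remission: int = 108
    n_gray: int = 34
    n_gray_active: int = 21
    n_gray_remission: int = 13
    n_batches: int = 4
    n_proteins: int = 175
    peptides_per_protein: tuple[int, int] = (2, 6)
    informative_proteins: tuple[tuple[str, float, int], ...] = DEFAULT_INFORMATIVE
    n_contaminants: int = 5
    # log2-scale intensity model
    baseline_log2_mean: float = 20.0
    protein_baseline_sd: float = 1.5
    peptide_offset_sd: float = 1.0
    protein_latent_sd: float = 1.0
    peptide_noise_sd: float = 0.5
    # per-batch additive offset and multiplicative residual scale (log2)
    batch_additive: tuple[float, ...] = (0.0, 0.8, -0.5, 0.4)
    batch_scale: tuple[float, ...] = (1.0, 1.15, 0.9, 1.05)
    # dropout; mnar_midpoint=None disables the intensity-dependent part
    mnar_midpoint: float | None = 16.0
    mnar_slope: float = 1.0
    mcar_rate: float = 0.02
    # calprotectin ranges (µg/g)
    gray_fc_range: tuple[float, float] = (GRAY_ZONE_LOW, GRAY_ZONE_HIGH)
    nongray_fc_ranges: dict = field(
        default_factory=lambda: {ACTIVE: (250.5, 1800.0), REMISSION: (5.0, 99.5)}
    )
    seed: int = 0

    def validate(self) -> None:
        c = self
        if c.n_active + c.n_remission != c.n_samples:
            raise ConfigError("n_active + n_remission must equal n_samples")
        if c.n_gray_active + c.n_gray_remission != c.n_gray:
            raise ConfigError("n_gray_active + n_gray_remission must equal n_gray")
        if c.n_gray > c.n_samples:
            raise ConfigError("n_gray exceeds n_samples")
        if c.n_gray_active > c.n_active or c.n_gray_remission > c.n_remission:
            raise ConfigError("gray-zone cell exceeds its activity-class total")
        if c.peptides_per_protein[0] < 1 or c.peptides_per_protein[0] > c.peptides_per_protein[1]:
            raise ConfigError("peptides_per_protein must satisfy 1 <= min <= max")
        for prot, lfc, k in c.informative_proteins:
            if not np.isfinite(lfc):
                raise ConfigError(f"non-finite log2FC for {prot}")
            if k < 1:
                raise ConfigError(f"informative protein {prot} needs >= 1 peptide")
        if len(c.informative_proteins) > c.n_proteins:
            raise ConfigError("more informative proteins than proteins")
        if len(c.batch_additive) != c.n_batches or len(c.batch_scale) != c.n_batches:
            raise ConfigError("batch shift vectors must have one entry per batch")
        if not 0.0 <= c.mcar_rate <= 1.0:
            raise ConfigError("mcar_rate must be in [0, 1]")
        lo, hi = c.gray_fc_range
        if lo > hi or lo < 0:
            raise ConfigError("invalid gray_fc_range")
        for cls, (a, b) in c.nongray_fc_ranges.items():
            if a > b or a < 0:
                raise ConfigError(f"invalid non-gray FC range for {cls}")
            if not (b < GRAY_ZONE_LOW or a > GRAY_ZONE_HIGH):
                raise ConfigError(f"non-gray FC range for {cls} intersects the gray zone")


def _sample_table(config: CohortConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Build the per-sample annotation with exact marginals."""
    cells = [
        (ACTIVE, True, config.n_gray_active),
        (ACTIVE, False, config.n_active - config.n_gray_active),
        (REMISSION, True, config.n_gray_remission),
        (REMISSION, False, config.n_remission - config.n_gray_remission),
    ]
    rows: list[tuple[str, bool, int]] = []
    for activity, gray, n in cells:
        # round-robin batches inside each cell keeps classes balanced
        # across batches (technical batches are class-agnostic)
        start = int(rng.integers(config.n_batches))
        for i in range(n):
            rows.append((activity, gray, (start + i) % config.n_batches))
    order = rng.permutation(len(rows))
    rows = [rows[i] for i in order]

    width = len(str(len(rows)))
    records = []
    for i, (activity, gray, batch) in enumerate(rows):
        if gray:
            lo, hi = config.gray_fc_range
        else:
            lo, hi = config.nongray_fc_ranges[activity]
        fc = float(rng.uniform(lo, hi))
        records.append(
            {
                "sample_id": f"S{i + 1:0{width}d}",
                "activity": activity,
                "batch": f"B{batch + 1}",
                "fc_value": fc,
            }
        )
    return pd.DataFrame(records).set_index("sample_id")


def _feature_table(config: CohortConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Peptide annotation: informative proteins first, then nulls, then
    contaminant features exercising the contaminant filter."""
    rows = []

    def add_protein(protein: str, n_pep: int, lfc: float, contaminant: bool) -> None:
        for _ in range(n_pep):
            seq = "".join(rng.choice(AMINO_ACIDS, size=int(rng.integers(8, 16))))
            mod = "UniMod:4" if rng.random() < 0.1 else ""
            rows.append(
                {
                    "feature_id": f"Pep_{protein}_{int(rng.integers(1, 1000)):03d}",
                    "protein_id": protein,
                    "sequence": seq,
                    "modification": mod,
                    "is_contaminant": contaminant,
                    "log2fc": lfc,
                }
            )

    for protein, lfc, n_pep in config.informative_proteins:
        add_protein(protein, n_pep, lfc, False)
    n_null = config.n_proteins - len(config.informative_proteins)
    lo, hi = config.peptides_per_protein
    for j in range(n_null):
        add_protein(f"PNULL{j + 1:04d}", int(rng.integers(lo, hi + 1)), 0.0, False)
    for j in range(config.n_contaminants):
        add_protein(f"CONT{j + 1:02d}", 1, 0.0, True)

    table = pd.DataFrame(rows)
    # regenerated ids may collide; disambiguate deterministically
    table["feature_id"] = table["feature_id"] + np.where(
        table["feature_id"].duplicated(keep=False),
        "_" + table.groupby("feature_id").cumcount().astype(str),
        "",
    )
    return table.set_index("feature_id")


def generate_cohort(config: CohortConfig) -> tuple[PeptideMatrix, SampleAnnotation]:
    """Simulate a cohort on the log2 scale.

    The intensity model for peptide *f* of protein *p* in sample *s* is

    ``x_fs = L_ps + o_f + e_fs``

    with sample-level protein latent ``L_ps ~ N(b_p + lfc_p * 1[Active],
    protein_latent_sd**2)``, fixed peptide offset ``o_f`` and independent
    peptide noise ``e_fs``. The shared latent makes within-protein peptide
    correlation exceed between-protein correlation. Batch effects are
    applied afterwards as ``x + gamma_b + (delta_b - 1) * (x - mu_f)``
    (additive offset plus multiplicative residual scale, the model
    empirical-Bayes batch correction assumes), then MNAR/MCAR dropout.

    Returns the (possibly incomplete) matrix with ``log2_scale=True`` and
    the sample annotation whose marginals match the config exactly.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    samples = _sample_table(config, rng)
    features = _feature_table(config, rng)
    n_feat, n_samp = len(features), len(samples)

    protein_ids = features["protein_id"].to_numpy()
    unique_prot, prot_idx = np.unique(protein_ids, return_inverse=True)
    baselines = rng.normal(config.baseline_log2_mean, config.protein_baseline_sd, len(unique_prot))
    prot_lfc = (
        features.drop_duplicates("protein_id").set_index("protein_id")["log2fc"].loc[unique_prot]
    ).to_numpy()

    is_active = (samples["activity"] == ACTIVE).to_numpy()
    # protein latent per (protein, sample)
    latent_mean = baselines[:, None] + prot_lfc[:, None] * is_active[None, :]
    latents = rng.normal(latent_mean, config.protein_latent_sd)

    offsets = rng.normal(0.0, config.peptide_offset_sd, n_feat)
    noise = rng.normal(0.0, config.peptide_noise_sd, (n_feat, n_samp))
    x = latents[prot_idx, :] + offsets[:, None] + noise

    # batch location/scale on the log2 scale around the expected feature mean
    mu_f = (
        baselines[prot_idx]
        + offsets
        + prot_lfc[prot_idx] * (config.n_active / config.n_samples)
    )
    batch_num = samples["batch"].str.lstrip("B").astype(int).to_numpy() - 1
    add = np.asarray(config.batch_additive)[batch_num]
    scale = np.asarray(config.batch_scale)[batch_num]
    x = mu_f[:, None] + scale[None, :] * (x - mu_f[:, None]) + add[None, :]

    matrix = PeptideMatrix(
        intensities=pd.DataFrame(x, index=features.index, columns=samples.index),
        feature_annotation=features.drop(columns="log2fc"),
        log2_scale=True,
    )
    annotation = SampleAnnotation(samples)

    if config.mnar_midpoint is not None or config.mcar_rate > 0:
        matrix = inject_missingness(
            matrix,
            mnar_midpoint=config.mnar_midpoint,
            mnar_slope=config.mnar_slope,
            mcar_rate=config.mcar_rate,
            seed=int(rng.integers(2**31)),
        )
    return matrix, annotation


def inject_missingness(
    matrix: PeptideMatrix,
    mnar_midpoint: float | None,
    mnar_slope: float,
    mcar_rate: float,
    seed: int,
) -> PeptideMatrix:
    """Apply intensity-dependent (MNAR) and random (MCAR) dropout.

    Each cell with log2 intensity ``x`` drops out independently with
    probability ``1 - (1 - p_mnar)(1 - p_mcar)`` where
    ``p_mnar = logistic(-slope * (x - midpoint))`` — low-abundance
    peptides vanish preferentially, the signature of DIA dropout.
    ``mnar_midpoint=None`` disables the MNAR part.
    """
    if not 0.0 <= mcar_rate <= 1.0:
        raise ConfigError("mcar_rate must be in [0, 1]")
    if not matrix.log2_scale:
        raise ValidationError("inject_missingness expects a log2-scale matrix")
    rng = np.random.default_rng(seed)
    x = matrix.intensities.to_numpy(dtype=float)
    if mnar_midpoint is None:
        p_mnar = np.zeros_like(x)
    else:
        if mnar_slope < 0:
            raise ConfigError("mnar_slope must be >= 0")
        p_mnar = expit(-mnar_slope * (x - mnar_midpoint))
    p = 1.0 - (1.0 - p_mnar) * (1.0 - mcar_rate)
    drop = rng.random(x.shape) < p
    out = x.copy()
    out[drop] = np.nan
    values = pd.DataFrame(out, index=matrix.intensities.index, columns=matrix.intensities.columns)
    return matrix.with_values(values)


def simulate_protein_matrix(
    n_up: int,
    n_down: int,
    n_null: int,
    effect: float,
    sd: float,
    n_active: int,
    n_remission: int,
    seed: int,
) -> tuple[pd.DataFrame, SampleAnnotation]:
    """Two-group Gaussian protein matrix for differential-abundance checks.

    Plants ``n_up`` proteins at +``effect`` and ``n_down`` at -``effect``
    (log2 units, per-sample sd ``sd``) among ``n_null`` null proteins, with
    the study's group sizes. Calprotectin values are placed outside the
    gray zone (they play no role in the test)."""
    rng = np.random.default_rng(seed)
    n_prot = n_up + n_down + n_null
    n_samp = n_active + n_remission
    effects = np.concatenate([np.full(n_up, effect), np.full(n_down, -effect), np.zeros(n_null)])
    is_active = np.concatenate([np.ones(n_active, bool), np.zeros(n_remission, bool)])
    x = rng.normal(0.0, sd, (n_prot, n_samp)) + effects[:, None] * is_active[None, :]

    prot_ids = [f"P{i + 1:04d}" for i in range(n_prot)]
    samp_ids = [f"S{i + 1:03d}" for i in range(n_samp)]
    values = pd.DataFrame(x, index=prot_ids, columns=samp_ids)
    ann = SampleAnnotation(
        pd.DataFrame(
            {
                "activity": np.where(is_active, ACTIVE, REMISSION),
                "batch": "B1",
                "fc_value": np.where(is_active, 500.0, 50.0),
            },
            index=pd.Index(samp_ids, name="sample_id"),
        )
    )
    return values, ann
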