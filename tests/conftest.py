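import numpy as np
import pandas as pd
import pytest

from peptidia.cohort import CohortConfig, generate_cohort
from peptidia.containers import PeptideMatrix, SampleAnnotation


def make_matrix(values, feature_ids=None, sample_ids=None, log2=True, proteins=None,
                contaminant=None):
    """Hand-built PeptideMatrix from a 2-D array (NaN = missing)."""
    values = np.asarray(values, dtype=float)
    nf, ns = values.shape
    feats = list(feature_ids) if feature_ids is not None else [f"F{i}" for i in range(nf)]
    samps = list(sample_ids) if sample_ids is not None else [f"S{j}" for j in range(ns)]
    ann = pd.DataFrame(
        {
            "protein_id": proteins if proteins is not None else feats,
            "sequence": "",
            "modification": "",
            "is_contaminant": contaminant if contaminant is not None else False,
        },
        index=pd.Index(feats),
    )
    return PeptideMatrix(
        intensities=pd.DataFrame(values, index=feats, columns=samps),
        feature_annotation=ann,
        log2_scale=log2,
    )


def make_annotation(activities, batches=None, fc=None):
    n = len(activities)
    ids = [f"S{j}" for j in range(n)]
    fc_vals = fc if fc is not None else [500.0 if a == "Active" else 50.0 for a in activities]
    return SampleAnnotation(
        pd.DataFrame(
            {
                "activity": list(activities),
                "batch": batches if batches is not None else "B1",
                "fc_value": fc_vals,
            },
            index=pd.Index(ids, name="sample_id"),
        )
    )


@pytest.fixture(scope="session")
def small_cohort():
    """80-sample, 30-protein cohort with batches and dropout."""
    cfg = CohortConfig(
        n_samples=80, n_active=32, n_remission=48,
        n_gray=16, n_gray_active=10, n_gray_remission=6,
        n_batches=2, batch_additive=(0.0, 0.6), batch_scale=(1.0, 1.1),
        n_proteins=30, peptides_per_protein=(2, 4), n_contaminants=2, seed=11,
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def paper_cohort():
    """Full study composition (174 samples, 175 proteins, 4 batches)."""
    return generate_cohort(CohortConfig(seed=2))
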