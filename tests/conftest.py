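"""Shared fixtures and hand-made table builders."""

from __future__ import annotations

import numpy as np
import pytest

from driftqc import (
    BLANK,
    EXPERIMENTAL,
    QC,
    FeatureMeta,
    FeatureTable,
    SampleMeta,
    SyntheticSpec,
    generate_dataset,
)


def make_table(
    values,
    roles,
    batches=None,
    is_flags=None,
    conditioning=None,
    replicate_groups=None,
    clinical_groups=None,
):
    """Build a small FeatureTable by hand.

    ``values`` is an (n_samples x n_features) array (NaN = missing);
    ``roles`` a list of sample roles; the rest optional per-sample /
    per-feature annotations.  Sample ids are S1.., feature ids F1..;
    injection order is the row order.
    """
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    batches = batches or [1] * n
    conditioning = conditioning or [False] * n
    replicate_groups = replicate_groups or [None] * n
    clinical_groups = clinical_groups or [None] * n
    is_flags = is_flags or [False] * p
    samples = [
        SampleMeta(
            sample_id=f"S{i + 1}",
            batch=batches[i],
            injection_order=i + 1,
            role=roles[i],
            is_conditioning=conditioning[i],
            replicate_group=replicate_groups[i],
            clinical_group=clinical_groups[i],
        )
        for i in range(n)
    ]
    features = [
        FeatureMeta(
            feature_id=f"F{j + 1}",
            mz=100.0 + j,
            rt=1.0 + j,
            is_internal_standard=is_flags[j],
            is_name=f"IS{j + 1}" if is_flags[j] else None,
        )
        for j in range(p)
    ]
    return FeatureTable.from_records(values, samples, features)


@pytest.fixture(scope="session")
def small_dataset():
    """A small 2-batch synthetic cohort with replicates and missingness."""
    spec = SyntheticSpec(
        n_features=30,
        n_experimental_per_batch=20,
        n_replicate_pairs=3,
        n_low_is_samples=4,
        noise_cv=0.08,
        missing_rate_low=0.05,
        seed=42,
    )
    return generate_dataset(spec)


@pytest.fixture(scope="session")
def clean_dataset():
    """A fully observed, noise-moderate cohort (no MNAR dropout)."""
    spec = SyntheticSpec(
        n_features=25,
        n_experimental_per_batch=15,
        n_replicate_pairs=3,
        noise_cv=0.05,
        missing_rate_low=0.0,
        seed=7,
    )
    return generate_dataset(spec)
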