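"""Reading and writing feature tables as tab-separated text.

Three files describe one table: the abundance matrix (header row of
feature ids, first column of sample ids), the sample metadata and the
feature metadata, all TSV with "." as decimal separator.  Missing
measurements are empty cells on disk (configurable sentinel) and NaN in
memory, so "not detected" never collides with a measured zero.
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from .core import (
    FEATURE_META_COLUMNS,
    SAMPLE_META_COLUMNS,
    FeatureTable,
    TableValidationError,
)

__all__ = ["read_feature_table", "write_feature_table"]

_FLOAT_FMT = "%.12g"  # lossless to >= 12 significant digits


def read_feature_table(
    matrix_path: Union[str, Path],
    sample_meta_path: Union[str, Path],
    feature_meta_path: Union[str, Path],
    missing_sentinel: str = "",
) -> FeatureTable:
    """Read a feature table from its three TSV files.

    The matrix file's header row holds feature ids and its first column
    sample ids; metadata files are keyed by the same ids.  Cells equal to
    ``missing_sentinel`` (default: empty) parse as missing.  The returned
    table is sorted by injection order and fully validated.
    """
    na_values = [missing_sentinel] if missing_sentinel else []
    matrix = pd.read_csv(
        matrix_path,
        sep="\t",
        index_col=0,
        na_values=na_values,
        keep_default_na=True,
    )
    matrix.index = matrix.index.astype(str)
    matrix.columns = matrix.columns.astype(str)
    try:
        matrix = matrix.astype(float)
    except ValueError as exc:
        raise TableValidationError(f"non-numeric abundance value: {exc}") from exc

    samples = pd.read_csv(sample_meta_path, sep="\t", dtype={"sample_id": str})
    if "sample_id" not in samples.columns:
        raise TableValidationError("sample metadata lacks a sample_id column")
    samples = samples.set_index("sample_id")
    for col in SAMPLE_META_COLUMNS:
        if col not in samples.columns:
            if col in ("replicate_group", "clinical_group"):
                samples[col] = np.nan
            elif col == "is_conditioning":
                samples[col] = False
            else:
                raise TableValidationError(f"sample metadata lacks column {col!r}")
    samples = samples[SAMPLE_META_COLUMNS]
    samples["batch"] = samples["batch"].astype(int)
    samples["injection_order"] = samples["injection_order"].astype(int)
    samples["is_conditioning"] = (
        samples["is_conditioning"]
        .map({True: True, False: False, "True": True, "False": False, 1: True, 0: False})
        .fillna(False)
        .astype(bool)
    )
    for col in ("replicate_group", "clinical_group"):
        samples[col] = samples[col].astype(object).where(samples[col].notna(), None)

    features = pd.read_csv(feature_meta_path, sep="\t", dtype={"feature_id": str})
    if "feature_id" not in features.columns:
        raise TableValidationError("feature metadata lacks a feature_id column")
    features = features.set_index("feature_id")
    for col in FEATURE_META_COLUMNS:
        if col not in features.columns:
            if col == "is_name":
                features[col] = np.nan
            else:
                raise TableValidationError(f"feature metadata lacks column {col!r}")
    features = features[FEATURE_META_COLUMNS]
    features["is_internal_standard"] = (
        features["is_internal_standard"]
        .map({True: True, False: False, "True": True, "False": False, 1: True, 0: False})
        .fillna(False)
        .astype(bool)
    )
    features["is_name"] = features["is_name"].astype(object).where(
        features["is_name"].notna(), None
    )

    missing_samples = set(matrix.index) - set(samples.index)
    if missing_samples:
        raise TableValidationError(
            f"matrix sample_id {sorted(missing_samples)[0]!r} absent from sample metadata"
        )
    extra_samples = set(samples.index) - set(matrix.index)
    if extra_samples:
        raise TableValidationError(
            f"sample metadata id {sorted(extra_samples)[0]!r} has no matrix row"
        )
    if set(matrix.columns) != set(features.index):
        diff = set(matrix.columns) ^ set(features.index)
        raise TableValidationError(
            f"matrix / feature metadata id mismatch (e.g. {sorted(diff)[0]!r})"
        )

    # align metadata to matrix axes, then sort rows by injection order
    samples = samples.loc[matrix.index]
    features = features.loc[matrix.columns]
    table = FeatureTable(values=matrix, samples=samples, features=features)
    table = table.sort_by_injection_order()
    table.validate()
    return table


def write_feature_table(
    table: FeatureTable,
    out_dir: Union[str, Path],
    missing_sentinel: str = "",
    prefix: str = "",
) -> dict[str, Path]:
    """Write a table to ``out_dir`` as three TSV files.

    Returns a dict with keys ``matrix``, ``samples``, ``features`` mapping
    to the written paths.  Values are written with 12 significant digits;
    missing cells are written as ``missing_sentinel``.
    """
    out_dir = Path(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "matrix": out_dir / f"{prefix}matrix.tsv",
        "samples": out_dir / f"{prefix}samples.tsv",
        "features": out_dir / f"{prefix}features.tsv",
    }
    table.values.to_csv(
        paths["matrix"],
        sep="\t",
        index_label="sample_id",
        float_format=_FLOAT_FMT,
        na_rep=missing_sentinel,
    )
    table.samples.to_csv(
        paths["samples"], sep="\t", index_label="sample_id", na_rep=""
    )
    table.features.to_csv(
        paths["features"],
        sep="\t",
        index_label="feature_id",
        float_format=_FLOAT_FMT,
        na_rep="",
    )
    return paths
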