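"""Feature filtering, kNN imputation and sample-level QC screens.

The canonical cascade for a multi-batch untargeted LC-MS table is:
blank filter -> presence filter -> kNN imputation -> pooled-QC RSD
filter.  On top of that sit two sample-level screens: flagging samples
whose internal-standard channels are depressed (summed IS abundance
below mean - 2 SD) and excluding samples whose total useful signal (TUS)
lies outside mean +/- 3 SD of their batch.

Conditioning QC injections (the opening block run to stabilise the
system) are excluded from every QC statistic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import EXPERIMENTAL, QC, FeatureTable

__all__ = [
    "FilterReport",
    "blank_filter",
    "presence_filter",
    "knn_impute",
    "qc_rsd",
    "rsd_filter",
    "total_useful_signal",
    "exclude_tus_outliers",
    "flag_low_is",
]

logger = logging.getLogger("driftqc")


@dataclass
class FilterReport:
    """Bookkeeping for one filter stage."""

    stage: str
    features_before: int
    features_after: int
    removed_ids: list[str] = field(default_factory=list)
    samples_flagged: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.features_after > self.features_before:
            raise ValueError("features_after exceeds features_before")
        if self.features_before - self.features_after != len(self.removed_ids):
            raise ValueError("removed_ids does not reconcile with feature counts")

    @property
    def n_removed(self) -> int:
        return len(self.removed_ids)


def _report(stage: str, before: list[str], after: list[str],
            samples_flagged: list[str] | None = None) -> FilterReport:
    removed = [f for f in before if f not in set(after)]
    rep = FilterReport(
        stage=stage,
        features_before=len(before),
        features_after=len(after),
        removed_ids=removed,
        samples_flagged=samples_flagged or [],
    )
    logger.info(
        "%s: %d -> %d features (%d removed)%s",
        stage, rep.features_before, rep.features_after, rep.n_removed,
        f", {len(rep.samples_flagged)} samples flagged" if rep.samples_flagged else "",
    )
    return rep


def blank_filter(
    table: FeatureTable, mode: str = "any_detect", fold: float = 3.0
) -> tuple[FeatureTable, FilterReport]:
    """Remove background features using the solvent-blank injections.

    ``any_detect`` removes every feature with a non-missing value in any
    blank (the literal "not present in the blanks" rule).  ``fold_ratio``
    removes features whose median experimental abundance is below
    ``fold`` times the median blank abundance (missing blank values count
    as 0).  Blank and QC rows stay in the table; only columns drop.
    """
    if mode not in ("any_detect", "fold_ratio"):
        raise ValueError(f"unknown blank filter mode {mode!r}")
    blanks = table.values.loc[table.blank_mask().to_numpy()]
    if blanks.shape[0] == 0:
        raise ValueError("blank filter requires at least one BLANK row")
    before = list(table.values.columns)
    if mode == "any_detect":
        detected = blanks.notna().any(axis=0)
        keep = [f for f in before if not detected[f]]
    else:
        exp = table.values.loc[table.experimental_mask().to_numpy()]
        blank_med = blanks.fillna(0.0).median(axis=0)
        exp_med = exp.median(axis=0, skipna=True)
        keep = [f for f in before if not (exp_med[f] < fold * blank_med[f])]
    out = table.select_features(keep)
    return out, _report("blank_filter", before, keep)


def presence_filter(
    table: FeatureTable, qc_frac: float = 0.50, sample_frac: float = 0.75
) -> tuple[FeatureTable, FilterReport]:
    """Keep features detected in >qc_frac of QCs and >sample_frac of samples.

    Both inequalities are strict.  Conditioning QCs do not count towards
    the QC denominator; blanks count towards neither denominator.
    """
    qc = table.values.loc[table.qc_mask().to_numpy()]
    exp = table.values.loc[table.experimental_mask().to_numpy()]
    if qc.shape[0] == 0:
        raise ValueError("presence filter requires at least one counted QC row")
    if exp.shape[0] == 0:
        raise ValueError("presence filter requires at least one experimental row")
    qc_ok = qc.notna().mean(axis=0) > qc_frac
    exp_ok = exp.notna().mean(axis=0) > sample_frac
    before = list(table.values.columns)
    keep = [f for f in before if qc_ok[f] and exp_ok[f]]
    out = table.select_features(keep)
    return out, _report("presence_filter", before, keep)


def knn_impute(table: FeatureTable, k: int = 5) -> FeatureTable:
    """Replace missing values by the mean of the k nearest samples.

    Distances are Euclidean over the autoscaled complete features
    (features with no missing value), computed among experimental and
    counted-QC rows.  For each missing cell the k nearest rows that do
    have that feature supply the imputed mean.  Non-missing values are
    never altered; blank rows are left untouched.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    mask = (table.experimental_mask() | table.qc_mask()).to_numpy()
    sub = table.values.loc[mask]
    if not sub.isna().any().any():
        return table.copy()
    exp = table.values.loc[table.experimental_mask().to_numpy()]
    n_nonmissing = exp.notna().sum(axis=0)
    bad = n_nonmissing[n_nonmissing < k]
    if len(bad):
        raise ValueError(
            f"feature {bad.index[0]!r} has only {int(bad.iloc[0])} non-missing "
            f"experimental values (< k={k})"
        )
    complete = sub.columns[sub.notna().all(axis=0)]
    if len(complete) == 0:
        raise ValueError("no complete features available to define distances")
    Z = sub[complete].to_numpy(dtype=float)
    mean = Z.mean(axis=0)
    sd = Z.std(axis=0, ddof=1)
    keep = sd > 0
    if not keep.any():
        raise ValueError("all complete features have zero variance")
    Z = (Z[:, keep] - mean[keep]) / sd[keep]
    # pairwise squared Euclidean distances
    sq = np.sum(Z**2, axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (Z @ Z.T)
    np.fill_diagonal(d2, np.inf)

    X0 = sub.to_numpy(dtype=float)  # donor values: originals only
    X = X0.copy()
    missing = np.argwhere(np.isnan(X0))
    for r, f in missing:
        have = np.flatnonzero(~np.isnan(X0[:, f]))
        if len(have) < k:
            raise ValueError(
                f"feature {sub.columns[f]!r}: fewer than k donors with a value"
            )
        order = have[np.argsort(d2[r, have], kind="stable")]
        donors = order[:k]
        X[r, f] = X0[donors, f].mean()
    vals = table.values.copy()
    vals.loc[mask] = X
    return table.with_values(vals)


def qc_rsd(table: FeatureTable) -> pd.Series:
    """Per-feature relative standard deviation (%) over counted QCs.

    RSD_f = 100 * sd / mean with sample SD (n-1); missing QC values are
    excluded feature-wise.  A zero mean, or fewer than two usable QC
    values for a feature, yields +inf.
    """
    qc = table.values.loc[table.qc_mask().to_numpy()]
    if qc.shape[0] < 2:
        raise ValueError("qc_rsd requires at least two counted QC rows")
    mean = qc.mean(axis=0, skipna=True)
    sd = qc.std(axis=0, ddof=1, skipna=True)
    n = qc.notna().sum(axis=0)
    rsd = 100.0 * sd / mean
    rsd[(mean == 0) | (n < 2) | mean.isna()] = np.inf
    rsd.name = "qc_rsd"
    return rsd


def rsd_filter(
    table: FeatureTable, threshold: float = 30.0
) -> tuple[FeatureTable, FilterReport]:
    """Keep features with QC RSD strictly below ``threshold`` percent."""
    rsd = qc_rsd(table)
    before = list(table.values.columns)
    keep = [f for f in before if rsd[f] < threshold]
    out = table.select_features(keep)
    return out, _report("rsd_filter", before, keep)


def total_useful_signal(table: FeatureTable) -> pd.Series:
    """Per-sample total useful signal: sum over non-IS features.

    Missing values contribute 0.  Internal-standard channels are spiked,
    not biological, so they are excluded from the sum.
    """
    cols = table.non_is_feature_ids()
    tus = table.values[cols].fillna(0.0).sum(axis=1)
    tus.name = "tus"
    return tus


def exclude_tus_outliers(
    table: FeatureTable, n_sd: float = 3.0
) -> tuple[FeatureTable, FilterReport]:
    """Drop experimental samples with TUS outside mean +/- n_sd SD.

    Mean and SD are computed per batch over that batch's experimental
    samples; QC and blank rows are never removed.  A zero SD (all-equal
    TUS) removes nothing.
    """
    tus = total_useful_signal(table)
    exp_mask = table.experimental_mask()
    removed: list[str] = []
    for b in table.batches:
        in_batch = (table.samples["batch"] == b) & exp_mask
        ids = table.samples.index[in_batch]
        if len(ids) == 0:
            continue
        if len(ids) < 3:
            raise ValueError(f"batch {b}: need >= 3 experimental samples")
        t = tus[ids]
        m, s = t.mean(), t.std(ddof=1)
        if s == 0:
            continue
        out = ids[(t < m - n_sd * s) | (t > m + n_sd * s)]
        removed.extend(out)
    keep = [s for s in table.values.index if s not in set(removed)]
    out_table = table.select_samples(keep)
    before = list(table.values.columns)
    rep = _report("tus_outliers", before, before, samples_flagged=sorted(removed))
    return out_table, rep


def flag_low_is(table: FeatureTable, n_sd: float = 2.0) -> list[str]:
    """Flag experimental samples with a depressed internal-standard sum.

    The summed IS abundance per experimental sample (all batches pooled)
    is compared to mean - n_sd * SD; samples below the threshold are
    reported, not deleted.
    """
    is_cols = table.is_feature_ids()
    if not is_cols:
        raise ValueError("table has no internal-standard features")
    exp_ids = table.samples.index[table.experimental_mask()]
    if len(exp_ids) == 0:
        raise ValueError("no experimental samples to screen")
    sums = table.values.loc[exp_ids, is_cols].fillna(0.0).sum(axis=1)
    thr = sums.mean() - n_sd * sums.std(ddof=1)
    flagged = sorted(sums.index[sums < thr])
    logger.info("flag_low_is: %d of %d samples below mean - %g SD",
                len(flagged), len(exp_ids), n_sd)
    return flagged
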