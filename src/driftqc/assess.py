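"""Validation battery for normalization quality.

Four complementary checks quantify how well a multi-batch table has been
integrated: (1) PCA score plots on autoscaled data; (2) Euclidean
distances between cross-batch replicate pairs in PCA score space, tested
before vs after correction with a paired t-test; (3) Ward hierarchical
clustering of the replicate samples, counting pairs merged as immediate
siblings; (4) the distribution of per-feature pooled-QC RSDs; plus a
per-feature Mann-Whitney U comparison of two clinical groups whose
significant-feature count should grow once batch effects are removed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import linkage

from .core import FeatureTable
from .preprocess import qc_rsd

__all__ = [
    "PcaScores",
    "ReplicateDistanceResult",
    "HcaPairResult",
    "RsdHistogram",
    "GroupComparisonResult",
    "AssessmentReport",
    "pca_scores",
    "replicate_distance_test",
    "hca_pair_clustering",
    "rsd_distribution",
    "compare_groups",
    "venn_counts",
]

logger = logging.getLogger("driftqc")


@dataclass
class PcaScores:
    """PCA scores on autoscaled data with a deterministic sign convention."""

    scores: pd.DataFrame  # samples x components
    variance_explained: np.ndarray  # percent, non-increasing
    loadings: pd.DataFrame  # features x components


def _autoscale(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Centre and scale to unit variance; returns (Z, kept column mask)."""
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    keep = sd > 0
    Z = (X[:, keep] - mean[keep]) / sd[keep]
    return Z, keep


def pca_scores(
    table: FeatureTable, n_components: int = 2, include_qcs: bool = True
) -> PcaScores:
    """PCA of the autoscaled table via singular-value decomposition.

    Rows are the experimental samples plus, if ``include_qcs``, the
    counted QCs.  Zero-variance features are dropped (logged).  The sign
    of each component is fixed by making its largest-magnitude loading
    positive, so results are reproducible.
    """
    mask = table.experimental_mask()
    if include_qcs:
        mask = mask | table.qc_mask()
    sub = table.values.loc[mask.to_numpy()]
    if sub.isna().any().any():
        raise ValueError("pca_scores requires a table without missing values")
    X = sub.to_numpy(dtype=float)
    if n_components > min(X.shape):
        raise ValueError("n_components exceeds matrix rank bound")
    Z, keep = _autoscale(X)
    n_dropped = (~keep).sum()
    if n_dropped:
        logger.info("pca_scores: dropped %d zero-variance features", n_dropped)
    U, s, Vt = np.linalg.svd(Z, full_matrices=False)
    var = s**2
    var_pct = 100.0 * var / var.sum()
    scores = U[:, :n_components] * s[:n_components]
    load = Vt[:n_components].T
    for j in range(n_components):
        i_max = int(np.argmax(np.abs(load[:, j])))
        if load[i_max, j] < 0:
            load[:, j] = -load[:, j]
            scores[:, j] = -scores[:, j]
    comp_names = [f"PC{j + 1}" for j in range(n_components)]
    return PcaScores(
        scores=pd.DataFrame(scores, index=sub.index, columns=comp_names),
        variance_explained=var_pct[:n_components],
        loadings=pd.DataFrame(
            load, index=sub.columns[keep], columns=comp_names
        ),
    )


@dataclass
class ReplicateDistanceResult:
    """Per-pair PCA distances before/after correction plus a paired test."""

    distances: pd.DataFrame  # pair_id, distance_before, distance_after
    mean_before: float
    mean_after: float
    t_statistic: float
    p_value: float
    test: str = "paired_t"


def _pair_distance(scores: pd.DataFrame, a: str, b: str) -> float:
    if a not in scores.index or b not in scores.index:
        missing = a if a not in scores.index else b
        raise ValueError(f"pair member {missing!r} absent from score matrix")
    return float(np.linalg.norm(scores.loc[a] - scores.loc[b]))


def replicate_distance_test(
    scores_before: PcaScores,
    scores_after: PcaScores,
    pairs: Sequence[tuple[str, str]],
    use_wilcoxon: bool = False,
) -> ReplicateDistanceResult:
    """Test whether correction shrinks replicate-pair distances.

    Euclidean distances are measured in the score dimensions of each
    model; the two-sided paired t-test (or Wilcoxon signed-rank with
    ``use_wilcoxon``) compares before vs after.  Identical score sets
    report t=0, p=1.
    """
    if len(pairs) < 2:
        raise ValueError("need at least two replicate pairs")
    rows = []
    for a, b in pairs:
        rows.append(
            {
                "pair_id": f"{a}|{b}",
                "distance_before": _pair_distance(scores_before.scores, a, b),
                "distance_after": _pair_distance(scores_after.scores, a, b),
            }
        )
    df = pd.DataFrame(rows).set_index("pair_id")
    diff = df["distance_before"] - df["distance_after"]
    if np.allclose(diff, 0.0):
        t, p = 0.0, 1.0
        name = "wilcoxon" if use_wilcoxon else "paired_t"
    elif use_wilcoxon:
        res = stats.wilcoxon(df["distance_before"], df["distance_after"])
        t, p, name = float(res.statistic), float(res.pvalue), "wilcoxon"
    else:
        res = stats.ttest_rel(df["distance_before"], df["distance_after"])
        t, p, name = float(res.statistic), float(res.pvalue), "paired_t"
    return ReplicateDistanceResult(
        distances=df,
        mean_before=float(df["distance_before"].mean()),
        mean_after=float(df["distance_after"].mean()),
        t_statistic=t,
        p_value=p,
        test=name,
    )


@dataclass
class HcaPairResult:
    """Ward clustering of replicate samples and the sibling-pair count."""

    n_pairs_clustered: int
    n_pairs: int
    linkage_matrix: np.ndarray
    leaf_ids: list[str]


def hca_pair_clustering(
    table: FeatureTable,
    pairs: Sequence[tuple[str, str]],
) -> HcaPairResult:
    """Count replicate pairs merged as immediate siblings under Ward HCA.

    Clustering runs on the autoscaled abundance rows of the pair members
    only (the samples measured in all batches).  A pair "clusters" when
    its two members are each other's first merge partner; the full merge
    order is returned for inspecting near-miss (proximal-node) pairs.
    """
    if not pairs:
        raise ValueError("no replicate pairs given")
    ids = [s for pair in pairs for s in pair]
    if len(set(ids)) != len(ids):
        raise ValueError("pair members must be distinct")
    sub = table.select_samples(ids)
    X = sub.values.to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("hca_pair_clustering requires no missing values")
    Z, _ = _autoscale(X)
    link = linkage(Z, method="ward")
    leaf_ids = list(sub.values.index)
    pos = {s: i for i, s in enumerate(leaf_ids)}
    pair_sets = {frozenset(p) for p in pairs}
    n = len(leaf_ids)
    count = 0
    for i, j in link[:, :2].astype(int):
        if i < n and j < n and frozenset({leaf_ids[i], leaf_ids[j]}) in pair_sets:
            count += 1
    return HcaPairResult(
        n_pairs_clustered=count,
        n_pairs=len(pairs),
        linkage_matrix=link,
        leaf_ids=leaf_ids,
    )


@dataclass
class RsdHistogram:
    """Distribution of per-feature pooled-QC RSDs."""

    bin_edges: np.ndarray
    counts: np.ndarray
    n_below_30: int
    n_above_100: int
    rsd: pd.Series

    @property
    def n_features(self) -> int:
        return int(self.counts.sum())


DEFAULT_RSD_BINS = (0.0, 5.0, 10.0, 15.0, 20.0, 25.0, 30.0, 40.0, 50.0, 75.0, 100.0, np.inf)


def rsd_distribution(
    table: FeatureTable, bins: Sequence[float] = DEFAULT_RSD_BINS
) -> RsdHistogram:
    """Histogram the per-feature QC RSDs; flag the <30% and >100% tallies."""
    rsd = qc_rsd(table)
    edges = np.asarray(bins, dtype=float)
    finite_edges = edges.copy()
    vals = rsd.to_numpy(dtype=float)
    # np.histogram cannot take an infinite upper edge; clip instead
    if np.isinf(finite_edges[-1]):
        hi = max(np.nanmax(vals[np.isfinite(vals)], initial=0.0), edges[-2]) + 1.0
        finite_edges[-1] = hi
        vals = np.clip(vals, None, hi - 0.5)
    counts, _ = np.histogram(vals, bins=finite_edges)
    return RsdHistogram(
        bin_edges=edges,
        counts=counts,
        n_below_30=int((rsd < 30.0).sum()),
        n_above_100=int((rsd > 100.0).sum()),
        rsd=rsd,
    )


@dataclass
class GroupComparisonResult:
    """Per-feature Mann-Whitney U comparison of two sample groups."""

    p_values: pd.Series
    u_statistics: pd.Series
    alpha: float
    significant: list[str]

    @property
    def n_significant(self) -> int:
        return len(self.significant)


def compare_groups(
    table: FeatureTable,
    group_a: Sequence[str],
    group_b: Sequence[str],
    alpha: float = 0.05,
    bh_correct: bool = False,
) -> GroupComparisonResult:
    """Two-sided Mann-Whitney U test per feature between two groups.

    The exact null distribution is used when both groups have <= 8
    samples and the feature is tie-free; otherwise the normal
    approximation with tie and continuity correction.  No multiplicity
    correction by default (``bh_correct`` switches on Benjamini-
    Hochberg, applied to the significance call only).
    """
    a = list(group_a)
    b = list(group_b)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both groups need at least two samples")
    missing = [s for s in a + b if s not in table.values.index]
    if missing:
        raise ValueError(f"sample {missing[0]!r} not in table")
    A = table.values.loc[a]
    B = table.values.loc[b]
    if A.isna().any().any() or B.isna().any().any():
        raise ValueError("compare_groups requires no missing values")
    ps, us = {}, {}
    small = len(a) <= 8 and len(b) <= 8
    for fid in table.values.columns:
        x = A[fid].to_numpy(dtype=float)
        y = B[fid].to_numpy(dtype=float)
        tie_free = len(np.unique(np.concatenate([x, y]))) == len(x) + len(y)
        method = "exact" if (small and tie_free) else "asymptotic"
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
        ps[fid] = float(res.pvalue)
        us[fid] = float(res.statistic)
    p = pd.Series(ps, name="p_value")
    u = pd.Series(us, name="u_statistic")
    if bh_correct:
        order = p.sort_values().index
        m = len(p)
        thresh = {}
        passed = 0
        for rank, fid in enumerate(order, start=1):
            if p[fid] <= alpha * rank / m:
                passed = rank
        sig = list(order[:passed])
    else:
        sig = list(p.index[p < alpha])
    return GroupComparisonResult(
        p_values=p, u_statistics=u, alpha=alpha, significant=sorted(sig)
    )


def venn_counts(
    set_a: Sequence[str], set_b: Sequence[str]
) -> dict[str, int]:
    """Overlap summary between two significant-feature sets."""
    sa, sb = set(set_a), set(set_b)
    return {
        "only_a": len(sa - sb),
        "both": len(sa & sb),
        "only_b": len(sb - sa),
    }


@dataclass
class AssessmentReport:
    """Aggregated outcome of the validation battery."""

    rsd_histogram: RsdHistogram
    replicates: Optional[ReplicateDistanceResult]
    hca_before: Optional[HcaPairResult]
    hca_after: Optional[HcaPairResult]
    group_comparison: Optional[GroupComparisonResult]
    pc_variance_explained: np.ndarray

    def summary(self) -> dict:
        """A JSON-serialisable digest of the report."""
        out: dict = {
            "n_features": self.rsd_histogram.n_features,
            "rsd_below_30": self.rsd_histogram.n_below_30,
            "rsd_above_100": self.rsd_histogram.n_above_100,
            "pc_variance_explained": [
                round(float(v), 6) for v in self.pc_variance_explained
            ],
        }
        if self.replicates is not None:
            out["replicate_mean_distance_before"] = round(self.replicates.mean_before, 6)
            out["replicate_mean_distance_after"] = round(self.replicates.mean_after, 6)
            out["replicate_p_value"] = round(self.replicates.p_value, 6)
        if self.hca_before is not None:
            out["hca_pairs_clustered_before"] = self.hca_before.n_pairs_clustered
        if self.hca_after is not None:
            out["hca_pairs_clustered_after"] = self.hca_after.n_pairs_clustered
        if self.group_comparison is not None:
            out["n_significant_features"] = self.group_comparison.n_significant
        return out
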