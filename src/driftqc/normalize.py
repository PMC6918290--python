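"""Normalization strategies for multi-batch LC-MS feature tables.

Four corrections, all multiplicative (ratio-based):

* **IS-sum** — divide each sample by its summed internal-standard
  abundance (rescaled to the cohort median so magnitudes are preserved).
* **TUS** — divide each sample by its total useful signal, rescaled the
  same way.
* **QC-SVRC** — intra-batch drift correction: per feature and batch, fit
  an RBF-kernel support-vector regression of pooled-QC abundance against
  injection order, pick the kernel width by leave-one-out CV on the QCs,
  and divide every sample by the predicted drift curve (anchored at the
  batch QC median).
* **QC-norm** — inter-batch correction: divide each feature by the ratio
  of its batch QC median to its QC median pooled across batches, which
  makes the per-batch QC medians exactly equal.

``run_pipeline`` composes these in order and re-applies the QC RSD < 30%
feature filter after every step.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.svm import SVR

from .core import BLANK, FeatureTable
from .preprocess import FilterReport, qc_rsd, rsd_filter, total_useful_signal

__all__ = [
    "SvrcParams",
    "NormalizationResult",
    "PipelineStage",
    "normalize_is_sum",
    "normalize_tus",
    "qcsvrc_correct",
    "qcnorm_correct",
    "run_pipeline",
]

logger = logging.getLogger("driftqc")

METHODS = ("is_sum", "tus", "qcsvrc", "qcnorm")


@dataclass(frozen=True)
class SvrcParams:
    """Hyperparameters for QC-SVRC drift correction.

    ``epsilon_frac`` and ``c_frac`` scale the SVR tolerance tube and error
    penalty to each feature's per-batch QC median (the conventional
    "epsilon = 5%, C = 50% of QC intensity"), keeping the fit unit-free.
    ``gamma_grid`` is searched by leave-one-out cross-validation on the
    batch's QCs, minimising RMSE.
    """

    epsilon_frac: float = 0.05
    c_frac: float = 0.50
    gamma_grid: tuple[float, ...] = tuple(2.0**k for k in range(-3, 7))
    cv_scheme: str = "leave_one_out"

    def __post_init__(self) -> None:
        if self.epsilon_frac <= 0 or self.c_frac <= 0:
            raise ValueError("epsilon_frac and c_frac must be > 0")
        if not self.gamma_grid or any(g <= 0 for g in self.gamma_grid):
            raise ValueError("gamma_grid must be non-empty and positive")
        if self.cv_scheme != "leave_one_out":
            raise ValueError(f"unsupported cv_scheme {self.cv_scheme!r}")


@dataclass
class NormalizationResult:
    """A corrected table plus the factors that produced it."""

    table: FeatureTable
    method: str
    qc_rsd_before: pd.Series
    qc_rsd_after: pd.Series
    gamma: Optional[pd.DataFrame] = None  # features x batches (QC-SVRC)
    factors: Optional[pd.DataFrame] = None  # features x batches r (QC-norm)


@dataclass
class PipelineStage:
    """One step of a composed normalization pipeline."""

    method: str
    result: NormalizationResult
    rsd_report: Optional[FilterReport] = None


def _row_ratio_normalize(
    table: FeatureTable, divisor: pd.Series, method: str
) -> NormalizationResult:
    if (divisor <= 0).any() or divisor.isna().any():
        bad = divisor.index[(divisor <= 0) | divisor.isna()][0]
        raise ValueError(f"{method}: non-positive divisor for sample {bad!r}")
    before = qc_rsd(table)
    scale = divisor.median()
    vals = table.values.div(divisor, axis=0) * scale
    out = table.with_values(vals)
    return NormalizationResult(
        table=out, method=method, qc_rsd_before=before, qc_rsd_after=qc_rsd(out)
    )


def normalize_is_sum(table: FeatureTable) -> NormalizationResult:
    """Divide each sample by its summed IS abundance (median-rescaled).

    The IS columns themselves are normalized too, so the per-sample IS
    sum becomes constant across samples afterwards.
    """
    is_cols = table.is_feature_ids()
    if not is_cols:
        raise ValueError("is_sum normalization requires internal-standard features")
    i_s = table.values[is_cols].sum(axis=1, skipna=True)
    return _row_ratio_normalize(table, i_s, "is_sum")


def normalize_tus(table: FeatureTable) -> NormalizationResult:
    """Divide each sample by its total useful signal (median-rescaled)."""
    tus = total_useful_signal(table)
    return _row_ratio_normalize(table, tus, "tus")


def _loo_rmse(x: np.ndarray, y: np.ndarray, gamma: float,
              eps: float, C: float) -> float:
    errs = np.empty(len(y))
    idx = np.arange(len(y))
    for i in idx:
        mask = idx != i
        svr = SVR(kernel="rbf", gamma=gamma, epsilon=eps, C=C, tol=1e-3)
        svr.fit(x[mask], y[mask])
        errs[i] = svr.predict(x[i : i + 1])[0] - y[i]
    return float(np.sqrt(np.mean(errs**2)))


def qcsvrc_correct(
    table: FeatureTable, params: Optional[SvrcParams] = None
) -> NormalizationResult:
    """Intra-batch drift correction by QC-anchored support-vector regression.

    Independently per feature and batch: the counted-QC abundances are
    regressed on injection order (rescaled to [0, 1] within the batch)
    with an RBF-kernel SVR whose tolerance tube and penalty are
    ``epsilon_frac`` and ``c_frac`` of the QC median; the kernel width is
    chosen from ``gamma_grid`` by leave-one-out CV minimising RMSE.  Every
    sample is multiplied by (QC median / predicted drift) at its own
    injection.  Non-positive drift predictions fall back to the value at
    the nearest QC injection and, failing that, to the QC median
    (i.e. no correction).
    """
    if params is None:
        params = SvrcParams()
    qc_mask = table.qc_mask().to_numpy()
    vals = table.values.copy()
    order = table.samples["injection_order"].to_numpy(dtype=float)
    batches = table.samples["batch"].to_numpy()
    gamma_rec = pd.DataFrame(
        index=table.values.columns,
        columns=[f"batch_{b}" for b in table.batches],
        dtype=float,
    )
    before = qc_rsd(table)
    floor = 1e-9
    for b in table.batches:
        in_batch = batches == b
        t = order[in_batch]
        span = t.max() - t.min()
        tb = (t - t.min()) / (span if span > 0 else 1.0)
        qc_rows = qc_mask[in_batch]
        if qc_rows.sum() < 5:
            raise ValueError(f"batch {b}: QC-SVRC needs >= 5 counted QCs")
        sub = table.values.loc[in_batch]
        corrected = sub.to_numpy(dtype=float).copy()
        for j, fid in enumerate(sub.columns):
            y_all = sub[fid].to_numpy(dtype=float)
            qy = y_all[qc_rows]
            ok = np.isfinite(qy)
            if ok.sum() == 0:
                raise ValueError(f"batch {b}, feature {fid!r}: all QC values missing")
            if ok.sum() < 5:
                raise ValueError(
                    f"batch {b}, feature {fid!r}: fewer than 5 usable QC values"
                )
            xq = tb[qc_rows][ok].reshape(-1, 1)
            yq = qy[ok]
            m = float(np.median(yq))
            if m <= 0:
                raise ValueError(f"batch {b}, feature {fid!r}: non-positive QC median")
            eps = params.epsilon_frac * m
            C = params.c_frac * m
            best_g, best_rmse = None, np.inf
            for g in params.gamma_grid:
                rmse = _loo_rmse(xq, yq, g, eps, C)
                # strict improvement required: ties keep the smaller gamma
                if best_g is None or rmse < best_rmse * (1.0 - 1e-12):
                    best_g, best_rmse = g, rmse
            svr = SVR(kernel="rbf", gamma=best_g, epsilon=eps, C=C, tol=1e-3)
            svr.fit(xq, yq)
            d = svr.predict(tb.reshape(-1, 1))
            bad = d <= floor * m
            if bad.any():
                # fall back to the prediction at the nearest QC injection
                qc_t = xq[:, 0]
                qc_pred = svr.predict(xq)
                for i in np.flatnonzero(bad):
                    nearest = int(np.argmin(np.abs(qc_t - tb[i])))
                    d[i] = qc_pred[nearest]
                d[d <= floor * m] = m
            corrected[:, j] = y_all * m / d
            gamma_rec.loc[fid, f"batch_{b}"] = best_g
        vals.loc[in_batch] = corrected
    out = table.with_values(vals)
    return NormalizationResult(
        table=out,
        method="qcsvrc",
        qc_rsd_before=before,
        qc_rsd_after=qc_rsd(out),
        gamma=gamma_rec,
    )


def qcnorm_correct(table: FeatureTable) -> NormalizationResult:
    """Inter-batch correction by QC median ratios.

    For feature f and batch b the scaling factor is
    ``r[f, b] = median(QC_f in batch b) / median(QC_f pooled over all
    batches)`` and every sample of batch b is divided by ``r[f, b]``.
    Afterwards each feature's QC medians are equal across batches.
    """
    qc = table.values.loc[table.qc_mask().to_numpy()]
    qc_batches = table.samples.loc[qc.index, "batch"]
    pooled = qc.median(axis=0, skipna=True)
    if (pooled <= 0).any() or pooled.isna().any():
        bad = pooled.index[(pooled <= 0) | pooled.isna()][0]
        raise ValueError(f"qcnorm: non-positive pooled QC median for {bad!r}")
    r = pd.DataFrame(
        index=table.values.columns,
        columns=[f"batch_{b}" for b in table.batches],
        dtype=float,
    )
    before = qc_rsd(table)
    vals = table.values.copy()
    for b in table.batches:
        med_b = qc.loc[(qc_batches == b).to_numpy()].median(axis=0, skipna=True)
        if med_b.isna().any() or (med_b <= 0).any():
            bad = med_b.index[med_b.isna() | (med_b <= 0)][0]
            raise ValueError(
                f"qcnorm: batch {b} has no positive QC median for {bad!r}"
            )
        r[f"batch_{b}"] = med_b
        rows = (table.samples["batch"] == b).to_numpy()
        vals.loc[rows] = table.values.loc[rows].div(med_b / pooled, axis=1)
    r = r.div(pooled, axis=0)
    out = table.with_values(vals)
    return NormalizationResult(
        table=out,
        method="qcnorm",
        qc_rsd_before=before,
        qc_rsd_after=qc_rsd(out),
        factors=r,
    )


def run_pipeline(
    table: FeatureTable,
    methods: Sequence[str],
    svrc_params: Optional[SvrcParams] = None,
    rsd_threshold: float = 30.0,
    refilter: bool = True,
) -> tuple[NormalizationResult, list[PipelineStage]]:
    """Apply normalization methods in order, refiltering RSD after each.

    Blank rows are dropped at entry (they have no IS or biological
    signal, so ratio corrections are undefined for them; their role ends
    with the blank filter).  After every method the QC RSD < threshold
    feature filter is re-applied, so feature counts never increase.
    Returns the final result plus one :class:`PipelineStage` per method.
    """
    unknown = [m for m in methods if m not in METHODS]
    if unknown:
        raise ValueError(f"unknown normalization method {unknown[0]!r}")
    keep_rows = [s for s, r in table.samples["role"].items() if r != BLANK]
    current = table.select_samples(keep_rows)
    stages: list[PipelineStage] = []
    rsd0 = qc_rsd(current)
    for m in methods:
        if m == "is_sum":
            res = normalize_is_sum(current)
        elif m == "tus":
            res = normalize_tus(current)
        elif m == "qcsvrc":
            res = qcsvrc_correct(current, svrc_params)
        else:
            res = qcnorm_correct(current)
        report = None
        current = res.table
        if refilter:
            current, report = rsd_filter(current, rsd_threshold)
            res.table = current
        stages.append(PipelineStage(method=m, result=res, rsd_report=report))
        logger.info("pipeline stage %s: %d features remain", m, current.n_features)
    final = NormalizationResult(
        table=current,
        method="+".join(methods) if methods else "identity",
        qc_rsd_before=rsd0,
        qc_rsd_after=qc_rsd(current),
        gamma=next(
            (s.result.gamma for s in reversed(stages) if s.result.gamma is not None),
            None,
        ),
        factors=next(
            (s.result.factors for s in reversed(stages) if s.result.factors is not None),
            None,
        ),
    )
    return final, stages
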