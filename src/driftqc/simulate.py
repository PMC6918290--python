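"""Synthetic multi-batch LC-MS cohorts with known ground truth.

The generator emulates the structure of a large serum-metabolomics run
split over several batches: a worklist of conditioning QCs, interleaved
pooled-QC injections every few samples, solvent blanks and no-injection
runs; per-feature smooth intra-batch signal drift; per-feature
multiplicative between-batch response factors; multiplicative measurement
noise; detection-limit (MNAR) dropout; a subset of samples with depressed
internal-standard channels; and biological replicate pairs re-measured in
two batches.  Every systematic component is emitted as ground truth so
correction methods can be tested for parameter recovery.

The signal model for sample ``s`` and feature ``f`` is

    x[s, f] = comp[subject(s), f] * beta[f, batch(s)] * g[f, b](t_s)
              * L[s, f] * e[s, f]

with ``comp`` the subject's baseline composition (mu_f times log-normal
biological variation; internal standards are spiked so their composition
is exactly mu_f), ``beta`` the batch factor (1 in batch 1), ``g`` the
drift curve, ``L`` the low-IS depression factor and ``e`` log-normal
noise with a fixed coefficient of variation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import (
    BLANK,
    EXPERIMENTAL,
    NO_INJECTION,
    QC,
    FeatureMeta,
    FeatureTable,
    ISPanel,
    SampleMeta,
    default_is_panel,
)

__all__ = [
    "SyntheticSpec",
    "GroundTruth",
    "drift_curve",
    "generate_worklist",
    "assign_batches_stratified",
    "generate_dataset",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """All generator parameters; generation is a pure function of this.

    Defaults mirror the emulated study design: 2 batches of 82
    experimental serum samples, a pooled QC injected every 5 samples plus
    10 conditioning QCs per batch, 3 solvent blanks, 7 replicate pairs
    re-measured across batches, ~10% measurement CV.
    """

    n_batches: int = 2
    n_experimental_per_batch: int = 82
    n_features: int = 400  # non-IS features; 6 IS peak features are added
    qc_every: int = 5
    n_conditioning_qcs: int = 10
    n_blanks: int = 3
    n_replicate_pairs: int = 7
    # baseline abundance: mu_f ~ exp(Normal(baseline_log_mean, baseline_log_sd))
    baseline_log_mean: float = 11.0
    baseline_log_sd: float = 1.0
    # between-subject biological variation (log-sd); IS channels have none
    sample_log_sd: float = 0.4
    # inter-batch multiplicative factor: log-normal sd (batch 1 fixed at 1)
    batch_factor_sd: float = 0.15
    # smooth intra-batch drift g(t) = exp(a*t + c*(1 - exp(-t/tau)))
    drift_sigma_a: float = 0.004  # per-injection linear log-slope sd
    drift_sigma_c: float = 0.35  # saturating-component amplitude sd
    drift_tau: float = 20.0  # injections; time constant of the fast component
    noise_cv: float = 0.10
    # MNAR dropout: cells in the lowest quantile go missing w.p. 0.8
    missing_rate_low: float = 0.05
    n_low_is_samples: int = 0
    low_is_factor: float = 0.1
    background_feature_fraction: float = 0.05
    blank_level: float = 0.05  # blank abundance as a fraction of mu_f
    clinical_groups: tuple[str, ...] = ("group_a", "group_b")
    seed: int = 0

    def validate(self) -> None:
        if self.n_batches < 1:
            raise ValueError("n_batches must be >= 1")
        if self.qc_every < 1:
            raise ValueError("qc_every must be >= 1")
        for name in (
            "n_experimental_per_batch",
            "n_features",
            "n_conditioning_qcs",
            "n_blanks",
            "n_replicate_pairs",
            "n_low_is_samples",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("missing_rate_low", "background_feature_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if self.n_replicate_pairs > 0 and self.n_batches < 2:
            raise ValueError("replicate pairs require at least 2 batches")
        if self.n_replicate_pairs > self.n_experimental_per_batch:
            raise ValueError("more replicate pairs than experimental slots per batch")


@dataclass
class GroundTruth:
    """The systematic components planted by :func:`generate_dataset`."""

    mu: pd.Series  # per-feature mean abundance
    beta: pd.DataFrame  # features x batches batch factors
    drift: pd.DataFrame  # samples x features drift factor g at each injection
    low_is_samples: list[str]
    background_features: list[str]
    replicate_pairs: list[tuple[str, str]]
    qc_composition: pd.Series  # the pooled-QC composition


def drift_curve(
    t: np.ndarray, a: float, c: float, tau: float
) -> np.ndarray:
    """Smooth multiplicative drift g(t) = exp(a*t + c*(1 - exp(-t/tau))).

    ``t`` is the within-batch injection index with t=0 at the batch's
    first injection, so g(0) = 1 exactly; g is positive and continuous.
    """
    t = np.asarray(t, dtype=float)
    return np.exp(a * t + c * (1.0 - np.exp(-t / tau)))


def generate_worklist(spec: SyntheticSpec) -> list[SampleMeta]:
    """The acquisition schedule, including runs that carry no data.

    Per batch: 3 no-injection runs, the solvent blanks, the conditioning
    QC block, then a repeating pattern of one QC followed by ``qc_every``
    experimental samples until the batch is exhausted, one closing QC and
    3 final no-injection runs.  Injection order is global and strictly
    increasing across batches.
    """
    spec.validate()
    worklist: list[SampleMeta] = []
    order = 0

    def add(sid: str, batch: int, role: str, conditioning: bool = False) -> None:
        nonlocal order
        order += 1
        worklist.append(
            SampleMeta(
                sample_id=sid,
                batch=batch,
                injection_order=order,
                role=role,
                is_conditioning=conditioning,
            )
        )

    for b in range(1, spec.n_batches + 1):
        for i in range(3):
            add(f"B{b}_NI{i + 1}", b, NO_INJECTION)
        for i in range(spec.n_blanks):
            add(f"B{b}_BLK{i + 1}", b, BLANK)
        qc_i = 0
        for _ in range(spec.n_conditioning_qcs):
            qc_i += 1
            add(f"B{b}_QC{qc_i:02d}", b, QC, conditioning=True)
        remaining = spec.n_experimental_per_batch
        samp_i = 0
        while remaining > 0:
            qc_i += 1
            add(f"B{b}_QC{qc_i:02d}", b, QC)
            for _ in range(min(spec.qc_every, remaining)):
                samp_i += 1
                add(f"B{b}_S{samp_i:03d}", b, EXPERIMENTAL)
            remaining -= min(spec.qc_every, remaining)
        qc_i += 1
        add(f"B{b}_QC{qc_i:02d}", b, QC)  # closing QC
        for i in range(3):
            add(f"B{b}_NI{i + 4}", b, NO_INJECTION)
    return worklist


def assign_batches_stratified(
    sample_groups: Sequence[tuple[str, str]],
    n_batches: int,
    seed: int,
) -> dict[str, int]:
    """Assign samples to batches, balancing every clinical group.

    Within each clinical group the per-batch counts differ by at most
    one; which samples land where is a seeded random permutation.
    """
    if not sample_groups:
        raise ValueError("no samples to assign")
    if n_batches < 1:
        raise ValueError("n_batches must be >= 1")
    rng = np.random.default_rng(seed)
    assignment: dict[str, int] = {}
    by_group: dict[str, list[str]] = {}
    for sid, grp in sample_groups:
        by_group.setdefault(grp, []).append(sid)
    for grp in sorted(by_group):
        members = sorted(by_group[grp])
        perm = rng.permutation(len(members))
        batch_order = rng.permutation(n_batches) + 1
        for i, j in enumerate(perm):
            assignment[members[j]] = int(batch_order[i % n_batches])
    return assignment


def _lognormal_noise(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Multiplicative noise with mean 1 and coefficient of variation cv."""
    if cv == 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv**2))
    return rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=size)


def generate_dataset(
    spec: SyntheticSpec, panel: Optional[ISPanel] = None
) -> tuple[FeatureTable, GroundTruth]:
    """Generate a multi-batch feature table plus its ground truth.

    Deterministic: the same spec (including seed) yields bit-identical
    output.  No-injection worklist entries carry no matrix row and are
    not part of the returned table.
    """
    spec.validate()
    if panel is None:
        panel = default_is_panel()
    rng = np.random.default_rng(spec.seed)

    # ---- features: IS peaks first, then regular features
    is_feats = panel.peak_features()
    n_is = len(is_feats)
    reg_feats = [
        FeatureMeta(
            feature_id=f"F{i + 1:04d}",
            mz=float(mz),
            rt=float(rt),
        )
        for i, (mz, rt) in enumerate(
            zip(
                rng.uniform(100.0, 1200.0, spec.n_features),
                rng.uniform(0.5, 35.0, spec.n_features),
            )
        )
    ]
    features = is_feats + reg_feats
    feature_ids = [f.feature_id for f in features]
    n_feat = len(features)

    # ---- per-feature mean abundance mu_f
    mu = np.empty(n_feat)
    # IS channels scale with spiked concentration (arbitrary response unit)
    for i, f in enumerate(is_feats):
        conc = next(c.concentration_mm for c in panel.entries if c.name == f.is_name)
        mu[i] = 2.0e5 * conc / 0.02
    mu[n_is:] = np.exp(
        rng.normal(spec.baseline_log_mean, spec.baseline_log_sd, spec.n_features)
    )

    # ---- batch factors beta (batch 1 = 1)
    beta = np.ones((n_feat, spec.n_batches))
    for b in range(1, spec.n_batches):
        beta[:, b] = np.exp(rng.normal(0.0, spec.batch_factor_sd, n_feat))

    # ---- drift parameters per feature per batch
    a = rng.normal(0.0, spec.drift_sigma_a, (n_feat, spec.n_batches))
    c = rng.normal(0.0, spec.drift_sigma_c, (n_feat, spec.n_batches))

    # ---- worklist; drop no-injection runs for the matrix
    worklist = generate_worklist(spec)
    injected = [w for w in worklist if w.role != NO_INJECTION]

    exp_by_batch: dict[int, list[SampleMeta]] = {}
    for w in injected:
        if w.role == EXPERIMENTAL:
            exp_by_batch.setdefault(w.batch, []).append(w)

    # ---- replicate pairs: slot i of batch 1 pairs with slot i of batch 2
    replicate_pairs: list[tuple[str, str]] = []
    rep_slot: dict[str, int] = {}  # sample_id -> subject index
    subject_of: dict[str, int] = {}
    subj_count = 0
    if spec.n_replicate_pairs > 0:
        b1 = exp_by_batch.get(1, [])
        b2 = exp_by_batch.get(2, [])
        pick1 = rng.choice(len(b1), spec.n_replicate_pairs, replace=False)
        pick2 = rng.choice(len(b2), spec.n_replicate_pairs, replace=False)
        for k, (i1, i2) in enumerate(zip(np.sort(pick1), np.sort(pick2))):
            sid1, sid2 = b1[i1].sample_id, b2[i2].sample_id
            replicate_pairs.append((sid1, sid2))
            subject_of[sid1] = subj_count
            subject_of[sid2] = subj_count
            rep_slot[sid1] = k
            rep_slot[sid2] = k
            subj_count += 1
    for b in sorted(exp_by_batch):
        for w in exp_by_batch[b]:
            if w.sample_id not in subject_of:
                subject_of[w.sample_id] = subj_count
                subj_count += 1

    # ---- subject compositions: mu * biological log-normal; IS exact
    comp = np.empty((subj_count, n_feat))
    bio = np.exp(rng.normal(0.0, spec.sample_log_sd, (subj_count, spec.n_features)))
    comp[:, :n_is] = mu[:n_is]  # IS spiked at fixed concentration
    comp[:, n_is:] = mu[n_is:] * bio

    # ---- QC composition: pooled mean of batch-1 experimental baselines
    b1_subjects = sorted({subject_of[w.sample_id] for w in exp_by_batch.get(1, [])})
    if b1_subjects:
        qc_comp = comp[b1_subjects].mean(axis=0)
    else:  # degenerate spec with no experimental samples
        qc_comp = mu.copy()

    # ---- clinical groups: stratified over non-replicate subjects
    clinical: dict[str, str] = {}
    if spec.clinical_groups:
        groups = list(spec.clinical_groups)
        exp_ids = [w.sample_id for b in sorted(exp_by_batch) for w in exp_by_batch[b]]
        perm = rng.permutation(len(exp_ids))
        for i, j in enumerate(perm):
            clinical[exp_ids[j]] = groups[i % len(groups)]

    # ---- low-IS samples: experimental, non-replicate
    candidates = [
        w.sample_id
        for b in sorted(exp_by_batch)
        for w in exp_by_batch[b]
        if w.sample_id not in rep_slot
    ]
    if spec.n_low_is_samples > len(candidates):
        raise ValueError("n_low_is_samples exceeds available experimental samples")
    low_is: list[str] = []
    if spec.n_low_is_samples > 0:
        pick = rng.choice(len(candidates), spec.n_low_is_samples, replace=False)
        low_is = sorted(candidates[i] for i in pick)

    # ---- background features present in blanks
    n_bg = int(round(spec.background_feature_fraction * spec.n_features))
    bg_idx = np.array([], dtype=int)
    if n_bg > 0:
        bg_idx = n_is + np.sort(
            rng.choice(spec.n_features, n_bg, replace=False)
        )
    background = [feature_ids[i] for i in bg_idx]

    # ---- assemble the matrix row by injection
    batch_start = {b: min(w.injection_order for w in worklist if w.batch == b)
                   for b in range(1, spec.n_batches + 1)}
    n_rows = len(injected)
    X = np.full((n_rows, n_feat), np.nan)
    drift_rows = np.ones((n_rows, n_feat))
    low_is_set = set(low_is)
    for r, w in enumerate(injected):
        b = w.batch
        t = w.injection_order - batch_start[b]
        g = np.exp(a[:, b - 1] * t + c[:, b - 1] * (1.0 - np.exp(-t / spec.drift_tau)))
        drift_rows[r] = g
        if w.role == BLANK:
            if len(bg_idx):
                base = np.full(n_feat, np.nan)
                base[bg_idx] = spec.blank_level * mu[bg_idx]
            else:
                base = np.full(n_feat, np.nan)
        elif w.role == QC:
            base = qc_comp.copy()
        else:  # EXPERIMENTAL
            base = comp[subject_of[w.sample_id]].copy()
        row = base * beta[:, b - 1] * g
        if w.sample_id in low_is_set:
            row[:n_is] *= spec.low_is_factor
        noise = _lognormal_noise(rng, spec.noise_cv, n_feat)
        X[r] = row * noise

    # ---- MNAR dropout on the low tail of QC + experimental cells
    if spec.missing_rate_low > 0:
        roles = np.array([w.role for w in injected])
        mask_rows = np.isin(roles, [QC, EXPERIMENTAL])
        cells = X[mask_rows]
        finite = np.isfinite(cells)
        if finite.any():
            q = np.quantile(cells[finite], spec.missing_rate_low)
            low = finite & (cells < q)
            drop = low & (rng.random(cells.shape) < 0.8)
            cells[drop] = np.nan
            X[mask_rows] = cells

    samples = [
        SampleMeta(
            sample_id=w.sample_id,
            batch=w.batch,
            injection_order=w.injection_order,
            role=w.role,
            is_conditioning=w.is_conditioning,
            replicate_group=(
                f"rep{rep_slot[w.sample_id] + 1:02d}" if w.sample_id in rep_slot else None
            ),
            clinical_group=clinical.get(w.sample_id),
        )
        for w in injected
    ]
    table = FeatureTable.from_records(X, samples, features)
    sample_ids = [w.sample_id for w in injected]
    truth = GroundTruth(
        mu=pd.Series(mu, index=feature_ids, name="mu"),
        beta=pd.DataFrame(
            beta,
            index=feature_ids,
            columns=[f"batch_{b}" for b in range(1, spec.n_batches + 1)],
        ),
        drift=pd.DataFrame(drift_rows, index=sample_ids, columns=feature_ids),
        low_is_samples=low_is,
        background_features=background,
        replicate_pairs=replicate_pairs,
        qc_composition=pd.Series(qc_comp, index=feature_ids, name="qc_composition"),
    )
    return table, truth
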