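"""End-to-end orchestration: simulate -> preprocess -> normalize -> assess.

A single :class:`PipelineConfig` (constructible from a YAML file) holds
every threshold, the normalization method order and a mandatory seed;
:func:`run_all` executes the stages in order, writes every intermediate
table and report to the output directory, and is bit-for-bit
deterministic for a fixed config.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from .assess import (
    AssessmentReport,
    compare_groups,
    hca_pair_clustering,
    pca_scores,
    replicate_distance_test,
    rsd_distribution,
)
from .core import FeatureTable
from .io import read_feature_table, write_feature_table
from .normalize import SvrcParams, run_pipeline
from .preprocess import (
    FilterReport,
    blank_filter,
    exclude_tus_outliers,
    flag_low_is,
    knn_impute,
    presence_filter,
    rsd_filter,
)
from .simulate import SyntheticSpec, generate_dataset

__all__ = ["PipelineConfig", "run_all", "artifact_digests"]

logger = logging.getLogger("driftqc")


@dataclass(frozen=True)
class PipelineConfig:
    """Every setting of the pipeline, with study defaults.

    ``seed`` has no default: reproducibility requires it to be stated.
    Input tables may be given via ``input_paths`` (matrix, sample
    metadata, feature metadata TSVs); otherwise a synthetic cohort is
    generated from ``synthetic`` (whose seed is overridden by ``seed``).
    """

    seed: int
    synthetic: SyntheticSpec = field(default_factory=SyntheticSpec)
    input_paths: Optional[tuple[str, str, str]] = None
    blank_mode: str = "any_detect"
    blank_fold: float = 3.0
    qc_frac: float = 0.50
    sample_frac: float = 0.75
    knn_k: int = 5
    rsd_threshold: float = 30.0
    low_is_n_sd: float = 2.0
    tus_outlier_sd: float = 3.0
    svrc: SvrcParams = field(default_factory=SvrcParams)
    methods: tuple[str, ...] = ("qcsvrc", "qcnorm")
    n_components: int = 2
    alpha: float = 0.05

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "seed" not in d:
            raise ValueError("config must set a seed (reproducibility contract)")
        if "synthetic" in d:
            d["synthetic"] = SyntheticSpec(**d["synthetic"])
        if "svrc" in d:
            sv = dict(d["svrc"])
            if "gamma_grid" in sv:
                sv["gamma_grid"] = tuple(float(g) for g in sv["gamma_grid"])
            d["svrc"] = SvrcParams(**sv)
        if "methods" in d:
            d["methods"] = tuple(d["methods"])
        if "input_paths" in d and d["input_paths"] is not None:
            d["input_paths"] = tuple(d["input_paths"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)


def _write_filter_reports(reports: Sequence[FilterReport], path: Path) -> None:
    rows = [
        {
            "stage": r.stage,
            "features_before": r.features_before,
            "features_after": r.features_after,
            "n_removed": r.n_removed,
            "removed_ids": ";".join(r.removed_ids),
            "samples_flagged": ";".join(r.samples_flagged),
        }
        for r in reports
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def run_all(config: PipelineConfig, out_dir: Union[str, Path]) -> dict:
    """Execute the full pipeline and write all artifacts under ``out_dir``.

    Stage order: data (simulated or loaded) -> blank filter -> presence
    filter -> kNN imputation -> QC-RSD filter -> low-IS flagging -> TUS
    outlier screen -> normalization chain (RSD-refiltered after each
    method) -> assessment battery.  Returns a summary dict (also written
    as ``summary.json``).  Identical config implies bit-identical output.
    """
    out_dir = Path(out_dir)
    os.makedirs(out_dir, exist_ok=True)

    # ---- stage 0: obtain the table
    if config.input_paths is not None:
        table = read_feature_table(*config.input_paths)
        truth = None
    else:
        spec = dataclasses.replace(config.synthetic, seed=config.seed)
        table, truth = generate_dataset(spec)
        write_feature_table(table, out_dir / "raw")
        truth.beta.to_csv(out_dir / "raw" / "ground_truth_beta.tsv", sep="\t",
                          float_format="%.12g")
        truth.mu.to_csv(out_dir / "raw" / "ground_truth_mu.tsv", sep="\t",
                        float_format="%.12g")
        pd.Series(truth.low_is_samples, name="sample_id").to_csv(
            out_dir / "raw" / "ground_truth_low_is.tsv", sep="\t", index=False
        )

    # ---- stage 1: filter cascade
    reports: list[FilterReport] = []
    filtered, rep = blank_filter(table, mode=config.blank_mode, fold=config.blank_fold)
    reports.append(rep)
    filtered, rep = presence_filter(filtered, config.qc_frac, config.sample_frac)
    reports.append(rep)
    filtered = knn_impute(filtered, k=config.knn_k)
    filtered, rep = rsd_filter(filtered, config.rsd_threshold)
    reports.append(rep)

    low_is = flag_low_is(filtered, n_sd=config.low_is_n_sd) if filtered.is_feature_ids() else []
    filtered, rep = exclude_tus_outliers(filtered, n_sd=config.tus_outlier_sd)
    reports.append(rep)
    write_feature_table(filtered, out_dir / "filtered")
    _write_filter_reports(reports, out_dir / "filter_reports.tsv")

    # ---- stage 2: normalization
    result, stages = run_pipeline(
        filtered,
        config.methods,
        svrc_params=config.svrc,
        rsd_threshold=config.rsd_threshold,
    )
    for st in stages:
        if st.rsd_report is not None:
            reports.append(st.rsd_report)
    write_feature_table(result.table, out_dir / "normalized")
    if result.gamma is not None:
        result.gamma.to_csv(out_dir / "svrc_gamma.tsv", sep="\t", float_format="%.12g")
    if result.factors is not None:
        result.factors.to_csv(out_dir / "qcnorm_factors.tsv", sep="\t",
                              float_format="%.12g")
    rsd_tab = pd.DataFrame(
        {
            "rsd_before": result.qc_rsd_before,
            "rsd_after": result.qc_rsd_after,
        }
    )
    rsd_tab.to_csv(out_dir / "qc_rsd.tsv", sep="\t", float_format="%.12g")
    _write_filter_reports(reports, out_dir / "filter_reports.tsv")

    # ---- stage 3: assessment
    # before/after tables restricted to the features surviving the chain
    before_tab = filtered.select_samples(list(result.table.values.index))
    before_tab = before_tab.select_features(list(result.table.values.columns))
    pairs = result.table.replicate_pairs()
    replicates = None
    hca_before = hca_after = None
    if len(pairs) >= 2:
        sc_before = pca_scores(before_tab, config.n_components, include_qcs=False)
        sc_after = pca_scores(result.table, config.n_components, include_qcs=False)
        replicates = replicate_distance_test(sc_before, sc_after, pairs)
        hca_before = hca_pair_clustering(before_tab, pairs)
        hca_after = hca_pair_clustering(result.table, pairs)
    groups = result.table.samples.loc[
        result.table.experimental_mask(), "clinical_group"
    ].dropna()
    comparison = None
    uniq = sorted(groups.unique())
    if len(uniq) >= 2:
        ga = list(groups.index[groups == uniq[0]])
        gb = list(groups.index[groups == uniq[1]])
        if len(ga) >= 2 and len(gb) >= 2:
            comparison = compare_groups(result.table, ga, gb, alpha=config.alpha)
    pca_all = pca_scores(result.table, config.n_components, include_qcs=True)
    report = AssessmentReport(
        rsd_histogram=rsd_distribution(result.table),
        replicates=replicates,
        hca_before=hca_before,
        hca_after=hca_after,
        group_comparison=comparison,
        pc_variance_explained=pca_all.variance_explained,
    )

    summary = {
        "seed": config.seed,
        "methods": list(config.methods),
        "low_is_flagged": low_is,
        "filters": [
            {
                "stage": r.stage,
                "features_before": r.features_before,
                "features_after": r.features_after,
                "n_samples_flagged": len(r.samples_flagged),
            }
            for r in reports
        ],
        "assessment": report.summary(),
    }
    with open(out_dir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    logger.info("run_all complete: %d features, %d samples",
                result.table.n_features, result.table.n_samples)
    return summary


def artifact_digests(out_dir: Union[str, Path]) -> dict[str, str]:
    """SHA-256 digest of every artifact file, keyed by relative path."""
    out_dir = Path(out_dir)
    digests = {}
    for p in sorted(out_dir.rglob("*")):
        if p.is_file():
            digests[str(p.relative_to(out_dir))] = hashlib.sha256(
                p.read_bytes()
            ).hexdigest()
    return digests
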