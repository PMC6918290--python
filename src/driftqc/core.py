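"""Core domain types for multi-batch LC-MS feature tables.

The central container is :class:`FeatureTable`: an abundance matrix
(samples x features) wrapped together with per-sample metadata (batch,
injection order, role) and per-feature metadata (m/z, retention time,
internal-standard flag).  Missing measurements are represented by NaN and
are distinct from measured zeros; every downstream stage (filtering,
imputation, drift correction, assessment) consumes and returns this type.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "QC",
    "BLANK",
    "EXPERIMENTAL",
    "NO_INJECTION",
    "ROLES",
    "SampleMeta",
    "FeatureMeta",
    "FeatureTable",
    "ISCompound",
    "ISPanel",
    "default_is_panel",
    "TableValidationError",
]

# Sample roles.  NO_INJECTION runs (mobile phase only) appear in worklists
# but never carry a matrix row, so a FeatureTable holds the other three.
QC = "QC"
BLANK = "BLANK"
EXPERIMENTAL = "EXPERIMENTAL"
NO_INJECTION = "NO_INJECTION"
ROLES = frozenset({QC, BLANK, EXPERIMENTAL, NO_INJECTION})

SAMPLE_META_COLUMNS = [
    "batch",
    "injection_order",
    "role",
    "is_conditioning",
    "replicate_group",
    "clinical_group",
]
FEATURE_META_COLUMNS = ["mz", "rt", "is_internal_standard", "is_name"]


class TableValidationError(ValueError):
    """A feature table or its metadata violates a structural invariant."""


@dataclass(frozen=True)
class SampleMeta:
    """Metadata for one injection.

    ``injection_order`` is global: strictly increasing over the whole
    multi-batch experiment.  ``is_conditioning`` marks the opening QC
    injections run to stabilise the system; those are excluded from all
    QC statistics.  ``replicate_group`` ties together re-measurements of
    the same biological sample (typically across batches).
    """

    sample_id: str
    batch: int
    injection_order: int
    role: str
    is_conditioning: bool = False
    replicate_group: Optional[str] = None
    clinical_group: Optional[str] = None

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise TableValidationError(
                f"sample {self.sample_id!r}: unknown role {self.role!r}"
            )
        if self.batch < 1:
            raise TableValidationError(
                f"sample {self.sample_id!r}: batch must be >= 1, got {self.batch}"
            )
        if self.injection_order < 1:
            raise TableValidationError(
                f"sample {self.sample_id!r}: injection_order must be >= 1"
            )


@dataclass(frozen=True)
class FeatureMeta:
    """Metadata for one LC-MS feature (an m/z, retention-time pair)."""

    feature_id: str
    mz: float
    rt: float
    is_internal_standard: bool = False
    is_name: Optional[str] = None

    def __post_init__(self) -> None:
        if self.mz <= 0 or self.rt <= 0:
            raise TableValidationError(
                f"feature {self.feature_id!r}: mz and rt must be positive"
            )
        if self.is_internal_standard and not self.is_name:
            raise TableValidationError(
                f"feature {self.feature_id!r}: internal-standard feature needs is_name"
            )


@dataclass(frozen=True)
class ISCompound:
    """One labelled internal standard; may elute as more than one peak."""

    name: str
    molecular_mass: float  # Da
    rts: tuple[float, ...]  # minutes, one entry per chromatographic peak
    modes: frozenset[str]  # subset of {"POS", "NEG"}
    concentration_mm: float  # spiked concentration, mM

    @property
    def n_peaks(self) -> int:
        return len(self.rts)


@dataclass(frozen=True)
class ISPanel:
    """The panel of labelled internal standards spiked into every sample."""

    entries: tuple[ISCompound, ...]

    @property
    def n_compounds(self) -> int:
        return len(self.entries)

    @property
    def n_peaks(self) -> int:
        return sum(c.n_peaks for c in self.entries)

    def peak_features(self) -> list[FeatureMeta]:
        """One FeatureMeta per chromatographic peak of the panel."""
        feats = []
        for comp in self.entries:
            for rt in comp.rts:
                feats.append(
                    FeatureMeta(
                        feature_id=f"IS_{comp.name}_rt{rt:.2f}",
                        mz=comp.molecular_mass,
                        rt=rt,
                        is_internal_standard=True,
                        is_name=comp.name,
                    )
                )
        return feats

    def names(self) -> list[str]:
        return [c.name for c in self.entries]


def default_is_panel() -> ISPanel:
    """The five-compound labelled IS mix used for system monitoring.

    Five deuterated / heavy-isotope compounds chosen to span the
    reverse-phase retention window (0.7-34.5 min) and a wide range of
    chemical classes (carnitine, amino acid, sphingolipid,
    lysophosphocholine, fatty acid).  LPC 18:1-D7 elutes as two peaks,
    so the panel contributes six chromatographic peaks in total.
    """
    return ISPanel(
        entries=(
            ISCompound("Carnitine-D3", 144.1454, (0.70,), frozenset({"POS"}), 0.02),
            ISCompound(
                "Isoleucine-13C-15N", 138.1118, (0.77,), frozenset({"POS", "NEG"}), 0.18
            ),
            ISCompound("Sphingosine-D7", 306.3264, (14.38,), frozenset({"POS"}), 0.02),
            ISCompound(
                "LPC18:1-D7", 528.3921, (19.30, 20.00), frozenset({"POS", "NEG"}), 0.01
            ),
            ISCompound("StearicAcid-D5", 289.3029, (34.54,), frozenset({"NEG"}), 0.17),
        )
    )


def _samples_frame(samples: Sequence[SampleMeta]) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in samples],
            "batch": [s.batch for s in samples],
            "injection_order": [s.injection_order for s in samples],
            "role": [s.role for s in samples],
            "is_conditioning": [bool(s.is_conditioning) for s in samples],
            "replicate_group": [s.replicate_group for s in samples],
            "clinical_group": [s.clinical_group for s in samples],
        }
    ).set_index("sample_id")
    return df


def _features_frame(features: Sequence[FeatureMeta]) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "feature_id": [f.feature_id for f in features],
            "mz": [f.mz for f in features],
            "rt": [f.rt for f in features],
            "is_internal_standard": [bool(f.is_internal_standard) for f in features],
            "is_name": [f.is_name for f in features],
        }
    ).set_index("feature_id")
    return df


@dataclass
class FeatureTable:
    """Abundance matrix plus sample and feature metadata.

    Attributes
    ----------
    values : pandas.DataFrame
        ``n_samples x n_features`` non-negative abundances; NaN marks a
        missing (not-detected) measurement and is distinct from 0.
        Rows are indexed by ``sample_id`` in injection order; columns by
        ``feature_id``.
    samples : pandas.DataFrame
        Indexed by ``sample_id``; columns ``batch``, ``injection_order``,
        ``role``, ``is_conditioning``, ``replicate_group``,
        ``clinical_group``.
    features : pandas.DataFrame
        Indexed by ``feature_id``; columns ``mz``, ``rt``,
        ``is_internal_standard``, ``is_name``.
    """

    values: pd.DataFrame
    samples: pd.DataFrame
    features: pd.DataFrame

    # ---------------------------------------------------------------- build
    @classmethod
    def from_records(
        cls,
        values: np.ndarray | pd.DataFrame,
        samples: Sequence[SampleMeta],
        features: Sequence[FeatureMeta],
    ) -> "FeatureTable":
        """Build and validate a table from metadata records and a matrix."""
        sdf = _samples_frame(samples)
        fdf = _features_frame(features)
        mat = np.asarray(values, dtype=float)
        if mat.ndim != 2:
            raise TableValidationError("abundance matrix must be 2-D")
        vals = pd.DataFrame(mat, index=sdf.index.copy(), columns=fdf.index.copy())
        table = cls(values=vals, samples=sdf, features=fdf)
        table = table.sort_by_injection_order()
        table.validate()
        return table

    # ------------------------------------------------------------ validation
    def validate(self) -> None:
        """Check all structural invariants; raise TableValidationError."""
        if list(self.values.index) != list(self.samples.index):
            raise TableValidationError("matrix rows do not match sample metadata ids")
        if list(self.values.columns) != list(self.features.index):
            raise TableValidationError(
                "matrix columns do not match feature metadata ids"
            )
        if self.samples.index.duplicated().any():
            dup = self.samples.index[self.samples.index.duplicated()][0]
            raise TableValidationError(f"duplicate sample_id {dup!r}")
        if self.features.index.duplicated().any():
            dup = self.features.index[self.features.index.duplicated()][0]
            raise TableValidationError(f"duplicate feature_id {dup!r}")
        order = self.samples["injection_order"].to_numpy()
        if len(order) and len(np.unique(order)) != len(order):
            raise TableValidationError("injection_order values are not unique")
        if len(order) and not np.all(np.diff(order) > 0):
            raise TableValidationError("rows are not sorted by injection_order")
        bad_role = ~self.samples["role"].isin(ROLES - {NO_INJECTION})
        if bad_role.any():
            sid = self.samples.index[bad_role][0]
            raise TableValidationError(
                f"sample {sid!r}: role {self.samples.loc[sid, 'role']!r} cannot "
                "carry a matrix row"
            )
        # batches must form contiguous runs in injection order
        batches = self.samples["batch"].to_numpy()
        seen: set[int] = set()
        prev = None
        for b in batches:
            if b != prev:
                if b in seen:
                    raise TableValidationError(
                        f"batch {b} is not a contiguous injection block"
                    )
                seen.add(b)
                prev = b
        with np.errstate(invalid="ignore"):
            neg = np.asarray(self.values.to_numpy() < 0)
        if neg.any():
            i, j = np.argwhere(neg)[0]
            raise TableValidationError(
                f"negative abundance at sample {self.values.index[i]!r}, "
                f"feature {self.values.columns[j]!r}"
            )
        is_mask = self.features["is_internal_standard"].astype(bool)
        missing_name = is_mask & self.features["is_name"].isna()
        if missing_name.any():
            fid = self.features.index[missing_name][0]
            raise TableValidationError(
                f"feature {fid!r}: internal-standard feature lacks is_name"
            )

    # -------------------------------------------------------------- accessors
    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def batches(self) -> list[int]:
        seen: list[int] = []
        for b in self.samples["batch"]:
            if b not in seen:
                seen.append(int(b))
        return seen

    def role_mask(self, role: str) -> pd.Series:
        return self.samples["role"] == role

    def qc_mask(self, counted_only: bool = True) -> pd.Series:
        """QC rows; by default excludes the conditioning injections."""
        m = self.role_mask(QC)
        if counted_only:
            m = m & ~self.samples["is_conditioning"].astype(bool)
        return m

    def experimental_mask(self) -> pd.Series:
        return self.role_mask(EXPERIMENTAL)

    def blank_mask(self) -> pd.Series:
        return self.role_mask(BLANK)

    def is_feature_ids(self) -> list[str]:
        """Feature ids flagged as internal standards."""
        m = self.features["is_internal_standard"].astype(bool)
        return list(self.features.index[m])

    def non_is_feature_ids(self) -> list[str]:
        m = self.features["is_internal_standard"].astype(bool)
        return list(self.features.index[~m])

    def replicate_pairs(self) -> list[tuple[str, str]]:
        """Replicate pairs (groups with exactly two member samples)."""
        grp = self.samples["replicate_group"].dropna()
        pairs = []
        for _, members in grp.groupby(grp):
            ids = sorted(members.index)
            if len(ids) == 2:
                pairs.append((ids[0], ids[1]))
        return sorted(pairs)

    # ------------------------------------------------------------- transforms
    def sort_by_injection_order(self) -> "FeatureTable":
        idx = self.samples["injection_order"].sort_values(kind="stable").index
        return FeatureTable(
            values=self.values.loc[idx],
            samples=self.samples.loc[idx],
            features=self.features,
        )

    def select_samples(self, sample_ids: Iterable[str]) -> "FeatureTable":
        """Row subset (order preserved from the current table)."""
        keep = set(sample_ids)
        idx = [s for s in self.values.index if s in keep]
        return FeatureTable(
            values=self.values.loc[idx],
            samples=self.samples.loc[idx],
            features=self.features,
        )

    def select_features(self, feature_ids: Iterable[str]) -> "FeatureTable":
        """Column subset (order preserved from the current table)."""
        keep = set(feature_ids)
        cols = [f for f in self.values.columns if f in keep]
        return FeatureTable(
            values=self.values[cols],
            samples=self.samples,
            features=self.features.loc[cols],
        )

    def with_values(self, values: pd.DataFrame) -> "FeatureTable":
        """Same metadata, new matrix (must share index/columns)."""
        if list(values.index) != list(self.values.index) or list(
            values.columns
        ) != list(self.values.columns):
            raise TableValidationError("replacement matrix has different axes")
        return FeatureTable(
            values=values.astype(float), samples=self.samples, features=self.features
        )

    def copy(self) -> "FeatureTable":
        return FeatureTable(
            values=self.values.copy(),
            samples=self.samples.copy(),
            features=self.features.copy(),
        )

    def equals(self, other: "FeatureTable") -> bool:
        """Exact equality including positions of missing values."""
        return (
            self.values.equals(other.values)
            and self.samples.equals(other.samples)
            and self.features.equals(other.features)
        )
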