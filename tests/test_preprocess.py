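"""Filter cascade, kNN imputation and sample-level QC screens."""

import numpy as np
import pytest

from driftqc import (
    BLANK,
    EXPERIMENTAL,
    QC,
    SyntheticSpec,
    blank_filter,
    exclude_tus_outliers,
    flag_low_is,
    generate_dataset,
    knn_impute,
    presence_filter,
    qc_rsd,
    rsd_filter,
    total_useful_signal,
)

from conftest import make_table

NA = np.nan


class TestBlankFilter:
    def test_any_detect_removes_feature_seen_in_one_blank(self):
        # F1 detected in one of three blanks; F2 in none
        vals = [
            [5.0, NA],
            [NA, NA],
            [NA, NA],
            [100.0, 50.0],
            [110.0, 55.0],
        ]
        t = make_table(vals, [BLANK, BLANK, BLANK, EXPERIMENTAL, EXPERIMENTAL])
        out, rep = blank_filter(t, mode="any_detect")
        assert list(out.values.columns) == ["F2"]
        assert rep.removed_ids == ["F1"]
        assert rep.features_before - rep.features_after == 1

    def test_fold_ratio_keeps_strong_signal(self):
        # blank median 10, sample median 100, fold 3: 100 >= 30 -> kept
        vals = [[10.0], [100.0], [100.0], [100.0]]
        t = make_table(vals, [BLANK, EXPERIMENTAL, EXPERIMENTAL, EXPERIMENTAL])
        out, rep = blank_filter(t, mode="fold_ratio", fold=3.0)
        assert out.n_features == 1
        # and a weak one is dropped: sample median 25 < 3*10
        vals2 = [[10.0], [25.0], [25.0], [25.0]]
        t2 = make_table(vals2, [BLANK, EXPERIMENTAL, EXPERIMENTAL, EXPERIMENTAL])
        out2, _ = blank_filter(t2, mode="fold_ratio", fold=3.0)
        assert out2.n_features == 0

    def test_requires_blank_rows(self):
        t = make_table([[1.0], [2.0]], [QC, EXPERIMENTAL])
        with pytest.raises(ValueError, match="BLANK"):
            blank_filter(t)

    def test_rows_retained_only_columns_drop(self, small_dataset):
        table, _ = small_dataset
        out, _ = blank_filter(table)
        assert out.n_samples == table.n_samples


class TestPresenceFilter:
    def test_exact_boundary_is_strict(self):
        """50% QC presence fails the strict >50% rule."""
        # 4 counted QCs; F1 present in exactly 2
        vals = [
            [1.0, 1.0],
            [NA, 1.0],
            [1.0, 1.0],
            [NA, 1.0],
            [1.0, 1.0],
            [1.0, 1.0],
        ]
        t = make_table(vals, [QC, QC, QC, QC, EXPERIMENTAL, EXPERIMENTAL])
        out, rep = presence_filter(t)
        assert rep.removed_ids == ["F1"]

    def test_sample_fraction_rule(self):
        """80% sample presence but 40% QC presence -> removed."""
        roles = [QC] * 5 + [EXPERIMENTAL] * 10
        col = [1.0, 1.0, NA, NA, NA] + [1.0] * 8 + [NA, NA]
        t = make_table(np.array(col).reshape(-1, 1), roles)
        out, rep = presence_filter(t)
        assert rep.removed_ids == ["F1"]

    def test_full_presence_kept(self):
        roles = [QC, QC, EXPERIMENTAL, EXPERIMENTAL]
        t = make_table(np.ones((4, 2)), roles)
        out, _ = presence_filter(t)
        assert out.n_features == 2

    def test_conditioning_qcs_not_counted(self):
        """A feature missing from all conditioning QCs but present in the
        counted QCs survives: conditioning injections are excluded."""
        roles = [QC, QC, QC, QC, EXPERIMENTAL, EXPERIMENTAL]
        cond = [True, True, False, False, False, False]
        col = [NA, NA, 1.0, 1.0, 1.0, 1.0]
        t = make_table(
            np.array(col).reshape(-1, 1), roles, conditioning=cond
        )
        out, _ = presence_filter(t)
        assert out.n_features == 1


def _brute_force_knn(values, k):
    """Independent oracle: exhaustive pairwise distances over autoscaled
    complete features; impute each hole from the k nearest donors."""
    X = np.array(values, dtype=float)
    complete = [j for j in range(X.shape[1]) if not np.isnan(X[:, j]).any()]
    Z = X[:, complete]
    Z = (Z - Z.mean(axis=0)) / Z.std(axis=0, ddof=1)
    out = X.copy()
    for i in range(X.shape[0]):
        for j in range(X.shape[1]):
            if np.isnan(X[i, j]):
                dists = []
                for r in range(X.shape[0]):
                    if r != i and not np.isnan(X[r, j]):
                        dists.append((np.sqrt(((Z[i] - Z[r]) ** 2).sum()), r))
                dists.sort()
                donors = [r for _, r in dists[:k]]
                out[i, j] = X[donors, j].mean()
    return out


class TestKnnImpute:
    def test_no_missing_returns_unchanged(self, clean_dataset):
        table, _ = clean_dataset
        out = knn_impute(table)
        assert out.equals(table)

    def test_constant_neighbours(self):
        vals = [
            [1.0, 7.0],
            [1.1, 7.0],
            [0.9, 7.0],
            [5.0, NA],
            [5.1, 7.0],
            [4.9, 7.0],
        ]
        t = make_table(vals, [EXPERIMENTAL] * 6)
        out = knn_impute(t, k=3)
        assert out.values.iloc[3, 1] == pytest.approx(7.0)

    def test_matches_brute_force_oracle(self):
        """6x3 hand table, k=2: imputed values equal the exhaustive
        nearest-neighbour oracle."""
        vals = [
            [1.0, 10.0, 5.0],
            [1.2, 11.0, NA],
            [0.8, 9.0, 4.0],
            [5.0, 50.0, 20.0],
            [5.5, NA, 22.0],
            [4.5, 45.0, 18.0],
        ]
        t = make_table(vals, [EXPERIMENTAL] * 6)
        out = knn_impute(t, k=2)
        expected = _brute_force_knn(vals, k=2)
        assert np.allclose(out.values.to_numpy(), expected)

    def test_non_missing_values_never_altered(self, small_dataset):
        table, _ = small_dataset
        sub, _ = presence_filter(blank_filter(table)[0])
        out = knn_impute(sub)
        orig = sub.values.to_numpy()
        new = out.values.to_numpy()
        mask = ~np.isnan(orig)
        assert np.array_equal(orig[mask], new[mask])

    def test_insufficient_donors_error(self):
        vals = [[1.0, NA], [2.0, NA], [3.0, 1.0], [4.0, NA]]
        t = make_table(vals, [EXPERIMENTAL] * 4)
        with pytest.raises(ValueError, match="non-missing"):
            knn_impute(t, k=2)

    def test_k_must_be_positive(self, clean_dataset):
        with pytest.raises(ValueError, match="k must be"):
            knn_impute(clean_dataset[0], k=0)


class TestQcRsd:
    def test_hand_value(self):
        """QC values (10, 12, 8): mean 10, sample SD 2 -> RSD 20%."""
        t = make_table(
            [[10.0], [12.0], [8.0], [1.0]], [QC, QC, QC, EXPERIMENTAL]
        )
        assert qc_rsd(t)["F1"] == pytest.approx(20.0)

    def test_constant_qcs_zero(self):
        t = make_table([[5.0], [5.0], [5.0]], [QC, QC, QC])
        assert qc_rsd(t)["F1"] == 0.0

    def test_zero_mean_is_infinite(self):
        t = make_table([[0.0], [0.0]], [QC, QC])
        assert np.isinf(qc_rsd(t)["F1"])

    def test_missing_excluded_pairwise(self):
        t = make_table([[10.0], [12.0], [8.0], [NA]], [QC, QC, QC, QC])
        assert qc_rsd(t)["F1"] == pytest.approx(20.0)

    def test_requires_two_qcs(self):
        t = make_table([[1.0]], [QC])
        with pytest.raises(ValueError, match="two counted QC"):
            qc_rsd(t)


class TestRsdFilter:
    def test_strict_boundary(self):
        """RSDs (5, 29.9, 30.0, 31)-ish: only strictly-below-30 survive."""
        rng = np.random.default_rng(0)

        def qc_col(rsd_pct, mean=100.0, n=40):
            # construct a column with an exact sample RSD
            base = rng.normal(0, 1, n)
            base = (base - base.mean()) / base.std(ddof=1)
            return mean + base * mean * rsd_pct / 100

        cols = np.column_stack([qc_col(r) for r in (5.0, 29.9, 30.0, 31.0)])
        t = make_table(np.abs(cols), [QC] * 40)
        rsd = qc_rsd(t)
        assert rsd.round(6).tolist() == [5.0, 29.9, 30.0, 31.0]
        out, rep = rsd_filter(t, threshold=30.0)
        assert list(out.values.columns) == ["F1", "F2"]

    def test_infinite_threshold_is_identity(self, clean_dataset):
        table, _ = clean_dataset
        out, rep = rsd_filter(table, threshold=np.inf)
        assert out.n_features == table.n_features

    def test_idempotent(self, clean_dataset):
        table, _ = clean_dataset
        once, _ = rsd_filter(table)
        twice, rep = rsd_filter(once)
        assert rep.n_removed == 0
        assert twice.equals(once)


class TestTus:
    def test_hand_sum(self):
        t = make_table([[1.0, 2.0], [3.0, 4.0]], [EXPERIMENTAL, EXPERIMENTAL])
        assert total_useful_signal(t).tolist() == [3.0, 7.0]

    def test_is_features_excluded(self):
        t = make_table(
            [[1.0, 100.0], [3.0, 100.0]],
            [EXPERIMENTAL, EXPERIMENTAL],
            is_flags=[False, True],
        )
        assert total_useful_signal(t).tolist() == [1.0, 3.0]

    def test_linearity(self, clean_dataset):
        table, _ = clean_dataset
        doubled = table.with_values(table.values * 2)
        assert np.allclose(
            total_useful_signal(doubled), 2 * total_useful_signal(table)
        )

    def test_missing_contributes_zero(self):
        t = make_table([[1.0, NA], [3.0, 4.0]], [EXPERIMENTAL, EXPERIMENTAL])
        assert total_useful_signal(t).tolist() == [1.0, 7.0]


class TestTusOutliers:
    def test_planted_outlier_removed(self):
        rng = np.random.default_rng(1)
        n = 30
        vals = rng.normal(100, 5, (n, 1)).clip(min=1)
        vals[7, 0] = 100 + 10 * 5  # mean + 10 SD, roughly
        t = make_table(vals, [EXPERIMENTAL] * n)
        out, rep = exclude_tus_outliers(t)
        assert "S8" in rep.samples_flagged
        assert out.n_samples == n - len(rep.samples_flagged)

    def test_all_equal_tus_no_outliers(self):
        t = make_table(np.full((5, 2), 3.0), [EXPERIMENTAL] * 5)
        out, rep = exclude_tus_outliers(t)
        assert rep.samples_flagged == []
        assert out.n_samples == 5

    def test_per_batch_thresholds(self):
        """Two batches at very different TUS levels: no sample is an
        outlier within its own batch even though globally half would be."""
        vals = np.concatenate(
            [np.full(10, 100.0), np.full(10, 10000.0)]
        ).reshape(-1, 1)
        rng = np.random.default_rng(2)
        vals = vals * rng.normal(1, 0.01, vals.shape)
        t = make_table(
            vals, [EXPERIMENTAL] * 20, batches=[1] * 10 + [2] * 10
        )
        out, rep = exclude_tus_outliers(t)
        assert rep.samples_flagged == []

    def test_qcs_never_removed(self):
        rng = np.random.default_rng(3)
        vals = rng.normal(100, 5, (12, 1)).clip(min=1)
        vals[0, 0] = 1e6  # a QC with absurd TUS
        roles = [QC] + [EXPERIMENTAL] * 11
        t = make_table(vals, roles)
        out, _ = exclude_tus_outliers(t)
        assert "S1" in out.values.index


class TestFlagLowIs:
    def test_planted_samples_flagged(self):
        spec = SyntheticSpec(
            n_features=20,
            n_experimental_per_batch=30,
            n_replicate_pairs=3,
            n_low_is_samples=6,
            noise_cv=0.1,
            missing_rate_low=0.0,
            seed=21,
        )
        table, truth = generate_dataset(spec)
        assert flag_low_is(table) == truth.low_is_samples

    def test_no_is_features_error(self):
        t = make_table([[1.0], [2.0]], [EXPERIMENTAL, EXPERIMENTAL])
        with pytest.raises(ValueError, match="internal-standard"):
            flag_low_is(t)

    def test_all_equal_sums_flag_nothing(self):
        t = make_table(
            np.ones((6, 2)),
            [EXPERIMENTAL] * 6,
            is_flags=[True, False],
        )
        assert flag_low_is(t) == []


class TestFilterBookkeeping:
    def test_counts_reconcile_across_cascade(self, small_dataset):
        table, _ = small_dataset
        t1, r1 = blank_filter(table)
        t2, r2 = presence_filter(t1)
        t3 = knn_impute(t2)
        t4, r4 = rsd_filter(t3)
        for rep in (r1, r2, r4):
            assert rep.features_before - rep.features_after == rep.n_removed
        assert r1.features_before == table.n_features
        assert r2.features_before == r1.features_after
        assert r4.features_before == r2.features_after
        assert t4.n_features == r4.features_after

    def test_surviving_values_bit_identical(self, small_dataset):
        """Filters subset rows/columns; surviving cells are untouched."""
        table, _ = small_dataset
        t1, _ = blank_filter(table)
        kept = t1.values.columns
        assert t1.values.equals(table.values[kept])
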