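"""Preprocessing contracts: filters, transforms, residualization, masking."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from plscvbm import (
    ExclusionRule,
    adjust_for_medication,
    apply_exclusions,
    build_voxel_block,
    residualize,
    standardize_columns,
    transform_predictors,
)
from plscvbm.preprocess import build_metabolic_block, default_exclusion_rules


def _toy_table(n=10, mmse=None):
    rng = np.random.default_rng(0)
    table = pd.DataFrame(
        {
            "subject_id": [f"s{i}" for i in range(n)],
            "bmi": rng.normal(27, 4, n),
            "crp": rng.lognormal(0.5, 0.8, n),
            "il6": rng.lognormal(1.0, 0.6, n),
            "adiponectin": rng.lognormal(8.7, 0.5, n),
            "leptin": rng.lognormal(2.2, 0.8, n),
            "age": rng.uniform(60, 79, n),
            "sex": rng.integers(0, 2, n),
        }
    )
    if mmse is not None:
        table["mmse"] = mmse
    return table


class TestExclusions:
    def test_mmse_filter_counts_and_survivors(self):
        table = _toy_table(10, mmse=[29, 26, 30, 28, 26, 30, 27, 28, 29, 30])
        kept, report = apply_exclusions(table, default_exclusion_rules())
        assert len(kept) == 8
        assert report.counts == {"mmse<27": 2}
        assert "s1" not in report.surviving_ids

    def test_no_rules_is_identity(self):
        table = _toy_table(6)
        kept, report = apply_exclusions(table, [])
        pd.testing.assert_frame_equal(kept, table)
        assert report.counts == {}

    def test_censored_rule_removes_exactly_the_clamped_subjects(self):
        table = _toy_table(100)
        idx = np.arange(100) % 14 == 3  # 7 subjects
        table.loc[idx, "il6"] = 1.5
        table.loc[~idx, "il6"] = np.maximum(table.loc[~idx, "il6"], 1.6)
        rule = ExclusionRule("il6_censored", "il6", "censored", 1.5)
        kept, report = apply_exclusions(table, [rule])
        assert report.counts["il6_censored"] == int(idx.sum()) == 7
        assert len(kept) == 93

    def test_missing_column_raises(self):
        with pytest.raises(KeyError, match="missing column"):
            apply_exclusions(_toy_table(5), [ExclusionRule("x", "nope", "min", 0)])


class TestTransforms:
    def test_natural_log_applied_to_assay_columns_only(self):
        table = _toy_table(5)
        table.loc[0, "crp"] = np.e
        table.loc[1, "leptin"] = 12.187
        out = transform_predictors(table)
        assert out.loc[0, "crp"] == pytest.approx(1.0)
        assert out.loc[1, "leptin"] == pytest.approx(np.log(12.187), abs=1e-4)
        assert out.loc[1, "leptin"] == pytest.approx(2.5004, abs=1e-3)
        pd.testing.assert_series_equal(out["bmi"], table["bmi"])

    def test_nonpositive_value_names_subject_and_column(self):
        table = _toy_table(5)
        table.loc[2, "crp"] = 0.0
        with pytest.raises(ValueError, match="crp.*s2"):
            transform_predictors(table)


class TestResidualize:
    def test_column_in_confound_span_residuals_vanish(self):
        rng = np.random.default_rng(1)
        age = rng.uniform(60, 79, 30)
        resid = residualize(2 * age, age)
        assert np.max(np.abs(resid)) < 1e-8

    def test_orthogonal_column_passes_through_centered(self):
        rng = np.random.default_rng(2)
        conf = rng.standard_normal((50, 2))
        col = rng.standard_normal(50)
        # orthogonalize col against confounds + intercept by construction
        design = np.column_stack([np.ones(50), conf])
        col = col - design @ np.linalg.lstsq(design, col, rcond=None)[0]
        out = residualize(col, conf)
        np.testing.assert_allclose(out[:, 0], col, atol=1e-10)

    def test_matches_hat_matrix_oracle(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal((50, 3))
        conf = rng.standard_normal((50, 2))
        design = np.column_stack([np.ones(50), conf])
        hat = design @ np.linalg.inv(design.T @ design) @ design.T
        expected = (np.eye(50) - hat) @ x
        np.testing.assert_allclose(residualize(x, conf), expected, atol=1e-10)

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_idempotent_and_orthogonal_to_confounds(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal((40, 4))
        conf = rng.standard_normal((40, 3))
        once = residualize(x, conf)
        np.testing.assert_allclose(residualize(once, conf), once, atol=1e-10)
        assert np.max(np.abs(conf.T @ once)) < 1e-8
        assert np.max(np.abs(once.sum(axis=0))) < 1e-8

    def test_rank_deficient_confounds_raise(self):
        rng = np.random.default_rng(4)
        conf = rng.standard_normal((20, 1))
        conf = np.column_stack([conf, 2 * conf])
        with pytest.raises(ValueError, match="rank deficient"):
            residualize(rng.standard_normal(20), conf)


class TestStandardize:
    def test_simple_column(self):
        np.testing.assert_allclose(
            standardize_columns(np.array([[1.0], [2.0], [3.0]]))[:, 0],
            [-1.0, 0.0, 1.0],
        )

    def test_already_standardized_unchanged(self):
        rng = np.random.default_rng(5)
        x = standardize_columns(rng.standard_normal((30, 3)))
        np.testing.assert_allclose(standardize_columns(x), x, atol=1e-12)

    def test_postcondition_exact(self):
        rng = np.random.default_rng(6)
        z = standardize_columns(rng.lognormal(size=(25, 4)))
        assert np.max(np.abs(z.mean(axis=0))) < 1e-10
        assert np.max(np.abs(z.std(axis=0, ddof=1) - 1)) < 1e-10

    def test_zero_variance_column_raises(self):
        x = np.column_stack([np.arange(5.0), np.ones(5)])
        with pytest.raises(ValueError, match="zero-variance.*\\[1\\]"):
            standardize_columns(x)


class TestMedicationAdjustment:
    def _table(self, n=40, seed=7):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(
            {
                "subject_id": [f"s{i}" for i in range(n)],
                "hba1c": rng.normal(5.5, 0.6, n),
                "total_chol": rng.normal(5.9, 1.1, n),
                "hdl": rng.normal(5.8, 1.1, n),
                "bmi": rng.normal(28, 4, n),
                "antidiabetic_flag": rng.integers(0, 2, n),
                "antihyperlipidemic_flag": rng.integers(0, 2, n),
            }
        )

    def test_all_flags_zero_merely_centers(self):
        table = self._table()
        table["antidiabetic_flag"] = 0
        out = adjust_for_medication(table)
        np.testing.assert_allclose(
            out["hba1c"], table["hba1c"] - table["hba1c"].mean(), atol=1e-10
        )

    def test_equals_group_mean_subtraction(self):
        table = self._table()
        out = adjust_for_medication(table)
        flag = table["antihyperlipidemic_flag"].to_numpy()
        for col in ("total_chol", "hdl"):
            vals = table[col].to_numpy()
            expected = vals.copy()
            for g in (0, 1):
                expected[flag == g] -= vals[flag == g].mean()
            np.testing.assert_allclose(out[col], expected, atol=1e-10)
        pd.testing.assert_series_equal(out["bmi"], table["bmi"])

    def test_flag_perfectly_predicting_value_zeroes_residuals(self):
        table = self._table()
        table["hba1c"] = np.where(table["antidiabetic_flag"] == 1, 8.0, 5.0)
        out = adjust_for_medication(table)
        assert np.max(np.abs(out["hba1c"])) < 1e-10

    def test_missing_flags_raise(self):
        with pytest.raises(KeyError, match="antidiabetic_flag"):
            adjust_for_medication(self._table().drop(columns="antidiabetic_flag"))


class TestVoxelBlock:
    def test_full_probability_keeps_all_voxels(self):
        imgs = np.random.default_rng(8).random((3, 4, 4, 4))
        raw, block = build_voxel_block(imgs, np.ones((4, 4, 4)), np.eye(4))
        assert block.v == 64
        assert raw.shape == (3, 64)

    def test_empty_mask_raises(self):
        imgs = np.zeros((3, 4, 4, 4))
        with pytest.raises(ValueError, match="empty mask"):
            build_voxel_block(imgs, np.zeros((4, 4, 4)), np.eye(4))

    def test_mask_size_matches_independent_count(self):
        rng = np.random.default_rng(9)
        prob = rng.random((20, 20, 15))
        expected = int(np.count_nonzero(prob >= 0.3))
        imgs = rng.random((2, 20, 20, 15))
        _, block = build_voxel_block(imgs, prob, np.eye(4))
        assert block.v == expected

    def test_grid_mismatch_raises(self):
        with pytest.raises(ValueError, match="does not match"):
            build_voxel_block(np.zeros((2, 3, 3, 3)), np.ones((4, 4, 4)), np.eye(4))

    def test_voxel_ordering_is_deterministic_raster(self):
        rng = np.random.default_rng(10)
        prob = rng.random((6, 5, 4))
        _, a = build_voxel_block(rng.random((2, 6, 5, 4)), prob, np.eye(4))
        _, b = build_voxel_block(rng.random((2, 6, 5, 4)), prob, np.eye(4))
        assert np.array_equal(a.voxel_indices, b.voxel_indices)
        # raster order: lexicographic in (i, j, k)
        order = np.lexsort((a.voxel_indices[:, 2], a.voxel_indices[:, 1], a.voxel_indices[:, 0]))
        assert np.array_equal(order, np.arange(a.v))


def test_standardization_after_residualization_keeps_orthogonality(small_cohort):
    table = transform_predictors(small_cohort.table)
    block = build_metabolic_block(small_cohort.table)
    conf = table[["age", "sex"]].to_numpy(float)
    conf_c = conf - conf.mean(axis=0)
    corr = np.corrcoef(np.column_stack([conf_c, block.X]), rowvar=False)
    cross = corr[:2, 2:]
    assert np.max(np.abs(cross)) < 1e-8
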