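import numpy as np
import pytest
from scipy import stats

from mmforecast.cohort import CohortDataset
from mmforecast.preprocess import (
    apply_power_transform,
    exclude_unmeasured,
    fit_power_transform,
    impute_trajectory,
    invert_power_transform,
    make_folds,
)

from conftest import make_trajectory


def _col_trajectory(column, col=5, patient_id="P0"):
    """Trajectory whose column `col` is given; everything else observed 1.0."""
    column = np.asarray(column, dtype=float)
    n = column.shape[0]
    values = np.ones((n, 10))
    mask = np.ones((n, 10), dtype=bool)
    obs = np.isfinite(column)
    values[:, col] = np.where(obs, column, 0.0)
    mask[:, col] = obs
    return make_trajectory(values, patient_id=patient_id, mask=mask)


class TestExcludeUnmeasured:
    def test_never_measured_feature_removes_patient(self):
        never = _col_trajectory([np.nan, np.nan, np.nan], patient_id="drop")
        kept = _col_trajectory([1.0, 2.0, 3.0], patient_id="keep")
        cohort = CohortDataset(trajectories=[never, kept])
        out, removed = exclude_unmeasured(cohort)
        assert removed == ["drop"]
        assert out.patient_ids == ["keep"]

    def test_single_late_measurement_retains_patient(self):
        # one beta2m value at the last visit only: "never measured" is the
        # sole exclusion criterion, so this patient stays
        column = [np.nan] * 9 + [2.5]
        cohort = CohortDataset(trajectories=[_col_trajectory(column)])
        out, removed = exclude_unmeasured(cohort)
        assert removed == []
        assert out.n_patients == 1

    def test_fully_observed_cohort_unchanged(self, small_cohort):
        full = CohortDataset(trajectories=[t.copy() for t in small_cohort])
        for t in full:
            t.observed_mask[:] = True
        out, removed = exclude_unmeasured(full)
        assert removed == []
        assert out.n_patients == full.n_patients

    def test_empty_result_raises(self):
        never = _col_trajectory([np.nan, np.nan])
        with pytest.raises(ValueError, match="empty"):
            exclude_unmeasured(CohortDataset(trajectories=[never]))


class TestImpute:
    def test_locf_with_leading_backfill(self):
        traj = _col_trajectory([np.nan, 2.0, np.nan, 3.0])
        out = impute_trajectory(traj)
        np.testing.assert_array_equal(out.values[:, 5], [2.0, 2.0, 2.0, 3.0])
        assert out.imputed_mask[:, 5].tolist() == [True, False, True, False]

    def test_pure_locf(self):
        traj = _col_trajectory([1.0, np.nan, np.nan])
        out = impute_trajectory(traj)
        np.testing.assert_array_equal(out.values[:, 5], [1.0, 1.0, 1.0])

    def test_fully_observed_noop(self):
        traj = _col_trajectory([1.0, 2.0, 3.0])
        out = impute_trajectory(traj)
        np.testing.assert_array_equal(out.values, traj.values)
        assert not out.imputed_mask.any()

    def test_zero_observations_raise(self):
        traj = _col_trajectory([np.nan, np.nan])
        with pytest.raises(ValueError, match="no observations"):
            impute_trajectory(traj)

    def test_prefix_causality_of_locf(self):
        """The imputed value at t depends only on visits <= t (except the
        leading backfill, which uses the earliest observation)."""
        col = [2.0, np.nan, 5.0, np.nan, np.nan, 7.0]
        base = impute_trajectory(_col_trajectory(col)).values[:, 5]
        # perturbing a future observation leaves earlier imputations unchanged
        col2 = list(col)
        col2[5] = 100.0
        pert = impute_trajectory(_col_trajectory(col2)).values[:, 5]
        np.testing.assert_array_equal(base[:5], pert[:5])

    def test_exclusion_then_imputation_is_finite(self, small_cohort):
        out, _ = exclude_unmeasured(small_cohort)
        for traj in out:
            imputed = impute_trajectory(traj)
            assert np.isfinite(imputed.values).all()


class TestPowerTransform:
    def test_gaussian_column_identity_exponent(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((5000, 1))
        params = fit_power_transform(x)
        assert abs(params.lambdas[0] - 1.0) < 0.1
        y = apply_power_transform(params, x)
        assert abs(y.mean()) < 0.05
        assert abs(y.std() - 1.0) < 0.05

    def test_lognormal_column_gaussianized(self):
        rng = np.random.default_rng(1)
        x = np.exp(0.5 * rng.standard_normal((5000, 1)))
        params = fit_power_transform(x)
        raw_skew = stats.skew(x[:, 0])
        y = apply_power_transform(params, x)
        assert abs(stats.skew(y[:, 0])) < 0.1 < raw_skew

    def test_round_trip_identity(self):
        rng = np.random.default_rng(2)
        x = np.abs(rng.standard_normal((200, 4))) * [1.0, 10.0, 100.0, 0.1]
        params = fit_power_transform(x)
        back = invert_power_transform(params, apply_power_transform(params, x))
        np.testing.assert_allclose(back, x, rtol=1e-8, atol=1e-10)

    def test_monotone_per_feature(self):
        rng = np.random.default_rng(3)
        x = rng.gamma(2.0, 2.0, size=(500, 2))
        params = fit_power_transform(x)
        y = apply_power_transform(params, x)
        for j in range(2):
            order = np.argsort(x[:, j])
            assert np.all(np.diff(y[order, j]) >= 0)

    def test_training_matrix_standardized(self):
        rng = np.random.default_rng(4)
        x = rng.gamma(3.0, 1.0, size=(1000, 3))
        params = fit_power_transform(x)
        y = apply_power_transform(params, x)
        np.testing.assert_allclose(y.mean(axis=0), 0.0, atol=1e-6)
        np.testing.assert_allclose(y.std(axis=0), 1.0, atol=1e-6)

    def test_fit_is_pure_function_of_training_rows(self):
        """No leakage: perturbing held-out rows cannot touch fitted params."""
        rng = np.random.default_rng(5)
        train = rng.gamma(2.0, 1.0, size=(300, 10))
        a = fit_power_transform(train)
        # a "test set" exists elsewhere and changes; params must be bitwise equal
        b = fit_power_transform(train.copy())
        np.testing.assert_array_equal(a.lambdas, b.lambdas)
        np.testing.assert_array_equal(a.means, b.means)
        np.testing.assert_array_equal(a.sds, b.sds)

    def test_constant_feature_raises_with_name(self):
        x = np.ones((50, 2))
        x[:, 0] = np.random.default_rng(6).standard_normal(50)
        with pytest.raises(ValueError, match="constant"):
            fit_power_transform(x, column_names=("ok", "flat"))

    def test_non_finite_input_raises_with_location(self):
        params = fit_power_transform(np.random.default_rng(7).gamma(2, 1, (50, 2)))
        bad = np.ones((3, 2))
        bad[1, 1] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            apply_power_transform(params, bad)

    def test_out_of_range_inverse_saturates(self):
        # a negative-lambda column bounds the transformed range above;
        # forecasts beyond the bound must invert to finite values
        rng = np.random.default_rng(8)
        x = np.exp(2 * rng.standard_normal((2000, 1)))  # heavy tail -> lambda < 0
        params = fit_power_transform(x)
        extreme = np.array([[10.0], [-10.0]])
        back = invert_power_transform(params, extreme)
        assert np.isfinite(back).all()


class TestMakeFolds:
    @staticmethod
    def _cohort(n):
        trajs = [
            make_trajectory(np.ones((2, 10)), patient_id=f"P{i:04d}") for i in range(n)
        ]
        return CohortDataset(trajectories=trajs)

    def test_875_patients_split_into_five_sets_of_175(self):
        split = make_folds(self._cohort(875), k=5, seed=0)
        assert [len(ids) for ids in split.test_ids] == [175] * 5

    def test_partition_property(self):
        cohort = self._cohort(10)
        split = make_folds(cohort, k=5, seed=1)
        seen = [p for ids in split.test_ids for p in ids]
        assert sorted(seen) == sorted(cohort.patient_ids)
        assert all(len(ids) == 2 for ids in split.test_ids)
        for fold in range(1, 6):
            assert set(split.train_ids(fold)).isdisjoint(split.fold_test_ids(fold))

    def test_seeded_reproducibility(self):
        cohort = self._cohort(20)
        a = make_folds(cohort, k=4, seed=3)
        b = make_folds(cohort, k=4, seed=3)
        assert a.test_ids == b.test_ids

    def test_k_exceeding_patients_raises(self):
        with pytest.raises(ValueError, match="exceeds"):
            make_folds(self._cohort(3), k=5, seed=0)
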