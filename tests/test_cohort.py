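import numpy as np
import pandas as pd
import pytest

from fcselect import (
    CohortSpec,
    ConnectivityFeatures,
    RegionMap,
    SyntheticCohort,
    VariableSpec,
    connectivity_features,
    inject_missingness,
    simulate_cohort,
    simulate_predictors_and_outcome,
    simulate_roi_timeseries,
)
from fcselect.cohort import RoiTimeSeriesPanel


def region_corr(k: int, pairs: dict) -> np.ndarray:
    mat = np.eye(k)
    for (i, j), r in pairs.items():
        mat[i, j] = mat[j, i] = r
    return mat


class TestRoiTimeseries:
    def test_seed_determinism(self, small_spec):
        a = simulate_roi_timeseries(small_spec)
        b = simulate_roi_timeseries(small_spec)
        for sid in a.subjects:
            np.testing.assert_array_equal(a.data[sid], b.data[sid])

    def test_independent_regions_uncorrelated(self, two_region_map):
        spec = CohortSpec(
            n_subjects=50,
            n_timepoints=400,
            region_map=two_region_map,
            region_correlation=np.eye(2),
            temporal_ar=0.0,
            self_report=[VariableSpec("a", "continuous", 0.0)],
            self_report_corr=np.eye(1),
            true_beta={},
            mcar_rates={},
            by_design_rule=None,
            seed=21,
        )
        panel = simulate_roi_timeseries(spec)
        from fcselect import aggregate_regions

        agg = aggregate_regions(panel, two_region_map)
        rs = [np.corrcoef(agg.data[s], rowvar=False)[0, 1] for s in agg.subjects]
        assert abs(np.mean(rs)) < 0.05

    def test_region_correlation_recovered(self, two_region_map):
        spec = CohortSpec(
            n_subjects=100,
            n_timepoints=400,
            region_map=two_region_map,
            region_correlation=region_corr(2, {(0, 1): 0.6}),
            temporal_ar=0.3,
            self_report=[VariableSpec("a", "continuous", 0.0)],
            self_report_corr=np.eye(1),
            true_beta={},
            mcar_rates={},
            by_design_rule=None,
            seed=22,
        )
        panel = simulate_roi_timeseries(spec)
        from fcselect import aggregate_regions

        agg = aggregate_regions(panel, two_region_map)
        rs = [np.corrcoef(agg.data[s], rowvar=False)[0, 1] for s in agg.subjects]
        # ROI noise attenuates the region-level correlation slightly
        assert abs(np.mean(rs) - 0.6) < 0.1

    def test_non_positive_definite_matrix_named(self, two_region_map):
        with pytest.raises(ValueError, match="region_correlation"):
            CohortSpec(
                region_map=two_region_map,
                region_correlation=region_corr(2, {(0, 1): 1.2}),
                seed=0,
            )


def small_features(spec: CohortSpec) -> ConnectivityFeatures:
    return connectivity_features(simulate_roi_timeseries(spec), spec.region_map)


class TestPredictorsAndOutcome:
    def test_zero_noise_zero_beta_constant_outcome(self, small_spec):
        import dataclasses

        spec = dataclasses.replace(small_spec, true_beta={}, noise_sd=0.0)
        cohort = simulate_predictors_and_outcome(spec, small_features(spec))
        np.testing.assert_allclose(cohort.outcome, spec.intercept)

    def test_zero_noise_single_beta_perfect_correlation(self, small_spec):
        import dataclasses

        spec = dataclasses.replace(small_spec, true_beta={"sleep": 0.5}, noise_sd=0.0)
        cohort = simulate_predictors_and_outcome(spec, small_features(spec))
        r = np.corrcoef(cohort.truth["predictors"]["sleep"], cohort.outcome)[0, 1]
        assert abs(r) == pytest.approx(1.0, abs=1e-10)

    def test_single_predictor_closed_form_correlation(self, tiny_map):
        # beta=0.5, noise sd 1: corr(x, y) = 0.5/sqrt(0.25+1) ~ 0.447
        spec = CohortSpec(
            n_subjects=500,
            n_timepoints=30,
            region_map=tiny_map,
            self_report=[
                VariableSpec("x", "continuous", 0.0, 1.0),
                VariableSpec("z", "continuous", 0.0, 1.0),
            ],
            self_report_corr=np.eye(2),
            true_beta={"x": 0.5},
            noise_sd=1.0,
            intercept=0.0,
            mcar_rates={},
            by_design_rule=None,
            seed=33,
        )
        cohort = simulate_predictors_and_outcome(spec, small_features(spec))
        r = np.corrcoef(cohort.truth["predictors"]["x"], cohort.outcome)[0, 1]
        assert abs(r - 0.5 / np.sqrt(1.25)) < 0.1

    def test_beta_length_mismatch_reports_expected_count(self, small_spec):
        import dataclasses

        spec = dataclasses.replace(small_spec, true_beta=np.zeros(3))
        with pytest.raises(ValueError, match="expected 7"):  # 4 vars + 3 edges
            simulate_predictors_and_outcome(spec, small_features(spec))

    def test_count_outcome_bounded(self, small_spec):
        import dataclasses

        spec = dataclasses.replace(small_spec, outcome_family="count")
        cohort = simulate_predictors_and_outcome(spec, small_features(spec))
        assert cohort.outcome.between(0, 17).all()
        assert (cohort.outcome == cohort.outcome.round()).all()

    def test_binary_marginal_rate(self, small_spec):
        import dataclasses

        spec = dataclasses.replace(small_spec, n_subjects=2000)
        cohort = simulate_predictors_and_outcome(spec, small_features(spec))
        assert cohort.truth["predictors"]["gender"].mean() == pytest.approx(0.6, abs=0.05)


class TestInjectMissingness:
    def test_zero_rates_no_rule_all_observed(self, small_spec):
        import dataclasses

        spec = dataclasses.replace(small_spec, mcar_rates={}, by_design_rule=None)
        cohort = simulate_predictors_and_outcome(spec, small_features(spec))
        out = inject_missingness(cohort, spec)
        assert out.mask.all().all()

    def test_by_design_rule_hits_exactly_the_older_subjects(self, small_spec):
        """97 subjects over the age threshold -> exactly 97 deletions."""
        import dataclasses

        n = 569
        ages = np.full(n, 40.0)
        ages[:97] = 70.0
        idx = pd.Index([f"sub-{i:04d}" for i in range(n)], name="subject")
        table = pd.DataFrame({"age": ages, "depression": np.zeros(n)}, index=idx)
        cohort = SyntheticCohort(
            roi_panel=RoiTimeSeriesPanel(subjects=list(idx), data={s: np.zeros((2, 0)) for s in idx}, label_ids=[]),
            features=ConnectivityFeatures(subjects=list(idx), edge_labels=[], values=np.zeros((n, 0))),
            predictor_table=table,
            outcome=pd.Series(np.zeros(n), index=idx),
            truth={"beta": pd.Series(dtype=float), "predictors": table.copy()},
        )
        spec = dataclasses.replace(
            small_spec, n_subjects=n, mcar_rates={}, by_design_rule=("depression", 65.0)
        )
        out = inject_missingness(cohort, spec)
        assert int(out.predictor_table["depression"].isna().sum()) == 97
        assert out.predictor_table["age"].notna().all()

    def test_mcar_rate_within_binomial_bounds(self, small_spec):
        import dataclasses

        spec = dataclasses.replace(
            small_spec, n_subjects=569, mcar_rates={"stress": 0.18}, by_design_rule=None
        )
        cohort = simulate_predictors_and_outcome(spec, small_features(spec))
        out = inject_missingness(cohort, spec)
        n_missing = int(out.predictor_table["stress"].isna().sum())
        # Binomial(569, 0.18): mean 102.4, sd 9.2; 99% bounds
        assert 78 <= n_missing <= 126

    def test_observed_entries_unchanged(self, small_spec):
        cohort = simulate_predictors_and_outcome(small_spec, small_features(small_spec))
        out = inject_missingness(cohort, small_spec)
        obs = out.mask.to_numpy()
        np.testing.assert_array_equal(
            out.predictor_table.to_numpy()[obs],
            cohort.predictor_table.to_numpy()[obs],
        )
        assert out.truth["predictors"].notna().all().all()

    def test_rule_for_absent_variable_rejected(self, small_spec):
        import dataclasses

        spec = dataclasses.replace(small_spec, by_design_rule=("bdi", 65.0))
        cohort = simulate_predictors_and_outcome(spec, small_features(spec))
        with pytest.raises(ValueError, match="bdi"):
            inject_missingness(cohort, spec)


class TestCohortInvariants:
    def test_full_cohort_seed_determinism(self, small_spec):
        a = simulate_cohort(small_spec)
        b = simulate_cohort(small_spec)
        assert a.predictor_table.equals(b.predictor_table)
        assert a.outcome.equals(b.outcome)
        np.testing.assert_array_equal(a.features.values, b.features.values)

    def test_latent_correlation_recovered_at_large_n(self, tiny_map):
        """Unbounded continuous variables: empirical corr -> specified corr."""
        corr = np.array([[1.0, 0.5, -0.3], [0.5, 1.0, 0.2], [-0.3, 0.2, 1.0]])
        spec = CohortSpec(
            n_subjects=5000,
            n_timepoints=10,
            region_map=tiny_map,
            self_report=[
                VariableSpec("u", "continuous", 0.0, 1.0),
                VariableSpec("v", "continuous", 10.0, 2.0),
                VariableSpec("w", "continuous", -5.0, 0.5),
            ],
            self_report_corr=corr,
            true_beta={},
            mcar_rates={},
            by_design_rule=None,
            seed=44,
        )
        cohort = simulate_predictors_and_outcome(spec, small_features(spec))
        emp = cohort.truth["predictors"][["u", "v", "w"]].corr().to_numpy()
        assert np.abs(emp - corr).max() < 0.05
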