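"""Preprocessing: missingness filter, imputation, inverse normal transform."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from bascox.preprocess import (filter_by_missingness, impute_covariates,
                               impute_metabolites, inverse_normal_transform,
                               preprocess)
from bascox.simulate import BA_NAMES, CohortSpec, CohortTable, generate_cohort


def minimal_table(ba_values: dict, n=None) -> CohortTable:
    """A tiny cohort table carrying only what preprocessing needs."""
    n = n or len(next(iter(ba_values.values())))
    df = pd.DataFrame({
        "subject_id": [f"S{i}" for i in range(n)],
        "time_mace": np.linspace(1, 5, n), "event_mace": 1,
        "time_death": np.linspace(1, 5, n), "event_death": 0,
        "age": np.linspace(50, 80, n), "sex": 1, "bmi": 27.0, "smoking": 0,
        "hypertension": 0, "dyslipidemia": 0, "t2d": 0, "dx_ua": 1,
        "dx_stemi": 0, "dx_nstemi": 0, "statin": 0, "beta_blocker": 0,
        "aspirin": 0, "diuretic": 0, "oad": 0, "insulin": 0, "egfr": 80.0,
    })
    for name, vals in ba_values.items():
        df[name] = vals
    return CohortTable(data=df, provenance="synthetic")


class TestMissingnessFilter:
    def test_default_cohort_drops_exactly_the_high_missing_column(
            self, default_cohort):
        filtered, report = filter_by_missingness(default_cohort)
        assert list(report.removed_metabolites) == ["TUDCA"]
        assert report.removed_metabolites["TUDCA"] > 0.20
        assert len(filtered.ba_columns()) == 15

    def test_complete_table_is_identity(self):
        table = minimal_table({"CA": [1.0, 2.0, 3.0], "DCA": [2.0, 1.0, 4.0]})
        out, report = filter_by_missingness(table)
        assert not report.removed_metabolites
        pd.testing.assert_frame_equal(out.data, table.data)

    def test_zero_threshold_drops_any_column_with_a_gap(self):
        table = minimal_table({"CA": [1.0, np.nan, 3.0], "DCA": [2.0, 1.0, 4.0]})
        out, report = filter_by_missingness(table, threshold=0.0)
        assert list(report.removed_metabolites) == ["CA"]
        assert out.ba_columns() == ["DCA"]

    def test_no_metabolite_columns_raises(self):
        table = minimal_table({"CA": [1.0, 2.0, 3.0]})
        table.data = table.data.drop(columns=["CA"])
        with pytest.raises(ValueError, match="no metabolite"):
            filter_by_missingness(table)


class TestMetaboliteImputation:
    def test_complete_table_is_identity(self):
        table = minimal_table({"CA": [1.0, 2.0, 3.0], "DCA": [2.0, 1.0, 4.0]})
        out = impute_metabolites(table, seed=0)
        pd.testing.assert_frame_equal(out.data, table.data)

    @pytest.mark.parametrize("learner,max_tol,mean_tol", [
        ("bridge", 0.01, 0.005),
        ("knn", 0.02, 0.01),
    ])
    def test_deterministic_linear_relation_is_learned(self, learner, max_tol,
                                                      mean_tol):
        # y = 2x exactly: any consistent regressor recovers the blanked cells;
        # the linear learner to <1%, local/tree learners to their resolution
        rng = np.random.default_rng(8)
        n = 2_000
        x = rng.uniform(1.0, 5.0, n)
        y = 2.0 * x
        y_obs = y.copy()
        blank = rng.uniform(size=n) < 0.10
        y_obs[blank] = np.nan
        table = minimal_table({"CA": x, "DCA": y_obs})
        out = impute_metabolites(table, seed=0, learner=learner)
        imputed = out.data["DCA"].to_numpy()[blank]
        rel_err = np.abs(imputed - y[blank]) / y[blank]
        assert np.max(rel_err) < max_tol
        assert np.mean(rel_err) < mean_tol

    def test_trees_learner_tracks_a_deterministic_relation(self):
        # randomized trees are coarser than the linear learner but must still
        # track the relation closely away from pure noise
        rng = np.random.default_rng(8)
        n = 2_000
        x = rng.uniform(1.0, 5.0, n)
        y_obs = 2.0 * x
        blank = rng.uniform(size=n) < 0.10
        y_obs = np.where(blank, np.nan, y_obs)
        table = minimal_table({"CA": x, "DCA": y_obs})
        out = impute_metabolites(table, seed=0, learner="trees")
        imputed = out.data["DCA"].to_numpy()[blank]
        assert np.corrcoef(imputed, 2.0 * x[blank])[0, 1] > 0.99

    def test_beats_mean_imputation_on_hidden_truth(self):
        # normalized RMSE on the log scale (the scale concentrations are
        # modeled on), pooled over cohorts to average over draw noise
        from bascox.simulate import simulate_cohort
        se_model, se_mean = [], []
        for seed in (11, 21, 31):
            cohort = simulate_cohort(CohortSpec(seed=seed))
            filtered, _ = filter_by_missingness(cohort)
            out = impute_metabolites(filtered, seed=seed)
            truth = cohort.truth
            for name in filtered.ba_columns():
                gap = filtered.data[name].isna().to_numpy()
                if not gap.any():
                    continue
                true_vals = np.log(truth[f"true_{name}"].to_numpy()[gap])
                col_mean = np.log(filtered.data[name]).mean()
                scale = np.log(truth[f"true_{name}"]).std()
                se_model.extend(
                    ((np.log(out.data[name].to_numpy()[gap]) - true_vals)
                     / scale) ** 2)
                se_mean.extend(((col_mean - true_vals) / scale) ** 2)
        assert np.sqrt(np.mean(se_model)) < np.sqrt(np.mean(se_mean))

    def test_observed_cells_never_altered(self, default_cohort):
        filtered, _ = filter_by_missingness(default_cohort)
        out = impute_metabolites(filtered, seed=11)
        for name in filtered.ba_columns():
            obs = filtered.data[name].notna()
            np.testing.assert_array_equal(out.data.loc[obs, name],
                                          filtered.data.loc[obs, name])
        assert out.data[filtered.ba_columns()].notna().all().all()

    def test_entirely_missing_column_raises(self):
        table = minimal_table({"CA": [np.nan] * 3, "DCA": [2.0, 1.0, 4.0]})
        with pytest.raises(ValueError, match="entirely missing"):
            impute_metabolites(table, seed=0)


class TestCovariateImputation:
    def test_complete_bmi_is_identity(self):
        table = minimal_table({"CA": [1.0, 2.0, 3.0], "DCA": [1.0, 2.0, 3.0]})
        out = impute_covariates(table, seed=0)
        pd.testing.assert_frame_equal(out.data, table.data)

    def test_bmi_gaps_filled_observed_untouched(self):
        spec = CohortSpec(seed=9)
        table = generate_cohort(spec)
        bmi = table.data["bmi"].to_numpy().copy()
        table.data.loc[: 4, "bmi"] = np.nan
        out = impute_covariates(table, seed=0)
        assert out.data["bmi"].notna().all()
        np.testing.assert_array_equal(out.data["bmi"].to_numpy()[5:], bmi[5:])

    def test_linear_bmi_age_relation_recovered(self):
        n = 400
        rng = np.random.default_rng(10)
        age = np.linspace(40, 90, n)
        bmi = 0.2 * age + 10.0
        table = minimal_table(
            {"CA": rng.uniform(1, 2, n), "DCA": rng.uniform(1, 2, n)}, n=n)
        table.data["age"] = age
        blank = rng.uniform(size=n) < 0.10
        bmi_obs = bmi.copy()
        bmi_obs[blank] = np.nan
        table.data["bmi"] = bmi_obs
        out = impute_covariates(table, seed=0)
        rel = np.abs(out.data["bmi"].to_numpy()[blank] - bmi[blank]) / bmi[blank]
        assert np.max(rel) < 0.01

    def test_non_bmi_covariate_missing_is_unsupported(self):
        table = minimal_table({"CA": [1.0, 2.0, 3.0], "DCA": [1.0, 2.0, 3.0]})
        table.data.loc[0, "egfr"] = np.nan
        with pytest.raises(ValueError, match="unsupported"):
            impute_covariates(table, seed=0)


class TestInverseNormalTransform:
    def test_median_rank_maps_to_zero(self):
        out = inverse_normal_transform([5.0, 1.0, 9.0])
        assert out[0] == pytest.approx(0.0, abs=1e-15)

    def test_maximum_maps_to_blom_quantile(self):
        # rank 3 of 3 with Blom offset: Phi^-1((3 - 3/8) / (3 + 1/4))
        out = inverse_normal_transform([5.0, 1.0, 9.0])
        expected = stats.norm.ppf((3 - 3 / 8) / 3.25)
        assert expected == pytest.approx(0.8694, abs=5e-5)
        assert out[2] == pytest.approx(expected, abs=1e-12)

    def test_mean_is_zero_by_antisymmetry(self):
        rng = np.random.default_rng(11)
        x = rng.normal(size=101)
        out = inverse_normal_transform(x)
        assert abs(out.mean()) < 1e-12

    def test_sd_close_to_but_below_one(self):
        rng = np.random.default_rng(12)
        for n in (100, 309):
            out = inverse_normal_transform(rng.uniform(size=n))
            assert 0.9 <= out.std(ddof=0) <= 1.0
        big = inverse_normal_transform(rng.uniform(size=10_000))
        assert abs(big.std(ddof=0) - 1.0) <= 0.02

    def test_ties_share_the_average_rank(self):
        out = inverse_normal_transform([1.0, 2.0, 2.0, 3.0])
        assert out[1] == pytest.approx(out[2], abs=0)
        assert out[0] < out[1] < out[3]

    @given(st.lists(st.integers(-10**6, 10**6), min_size=4, max_size=60,
                    unique=True))
    @settings(max_examples=50, deadline=None)
    def test_rank_equivariance_under_monotone_maps(self, values):
        x = np.asarray(values, dtype=float) / 1e3
        base = inverse_normal_transform(x)
        for f in (lambda v: np.exp(v / 1e4), lambda v: v ** 3 + 2 * v):
            np.testing.assert_allclose(
                inverse_normal_transform(f(x)), base, atol=1e-12)

    def test_strictly_monotone_for_tie_free_input(self):
        rng = np.random.default_rng(13)
        x = rng.normal(size=50)
        out = inverse_normal_transform(x)
        order = np.argsort(x)
        assert np.all(np.diff(out[order]) > 0)

    def test_constant_input_raises(self):
        with pytest.raises(ValueError, match="constant"):
            inverse_normal_transform([2.0, 2.0, 2.0])

    def test_configurable_offsets_differ(self):
        x = [3.0, 1.0, 2.0, 5.0]
        blom = inverse_normal_transform(x, offset="blom")
        rankit = inverse_normal_transform(x, offset=0.5)
        assert not np.allclose(blom, rankit)


class TestFullPreprocess:
    def test_pipeline_output_contract(self, prepped_cohort):
        table, report = prepped_cohort
        assert list(report.removed_metabolites) == ["TUDCA"]
        ba = table.ba_columns()
        assert len(ba) == 15
        values = table.data[ba]
        assert values.notna().all().all()
        means = values.mean().to_numpy()
        np.testing.assert_allclose(means, 0.0, atol=1e-12)
        sds = values.std(ddof=0).to_numpy()
        assert np.all((sds >= 0.9) & (sds <= 1.0))

    def test_idempotent_on_complete_table(self, prepped_cohort):
        table, _ = prepped_cohort
        again = impute_metabolites(table, seed=1)
        pd.testing.assert_frame_equal(again.data, table.data)
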