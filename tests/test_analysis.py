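"""Regression machinery against closed-form and brute-force oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from oracles import (
    anova_f,
    chi2_statistic,
    logistic_mle_grid,
    ols_normal_equations,
    pearson_r,
)

from frailsvd import CohortSpec, FrailtySVDModel, generate_cohort, transform_volume
from frailsvd.analysis import (
    FRAIL_TERM,
    PREFRAIL_TERM,
    correlate_volume_perfusion,
    demographics_table,
    fit_component_exploratory,
    fit_linear,
    fit_logistic,
    fit_shape_secondary,
    run_pipeline,
)


def _toy_df(n=12, seed=0, groups=("frail", "pre_frail", "non_frail")):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {
            "group": [groups[i % len(groups)] for i in range(n)],
            "age": rng.uniform(65, 85, n),
            "sex": rng.integers(0, 2, n),
            "icv_ml": rng.normal(1450, 100, n),
        }
    )


class TestTransformVolume:
    def test_known_values(self):
        assert transform_volume(1.0) == pytest.approx(np.log(100.0))
        assert transform_volume(0.01) == pytest.approx(0.0)

    def test_monotone(self):
        v = np.array([0.2, 0.5, 1.7, 9.0])
        assert np.all(np.diff(transform_volume(v)) > 0)

    def test_zero_maps_to_missing(self):
        assert np.isnan(transform_volume(0.0))

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            transform_volume(-1.0)


class TestLinearFit:
    def test_noiseless_effect_recovered_exactly(self):
        df = _toy_df(30, seed=1)
        df["y"] = 2.0 + 0.5 * (df.group == "frail") + 0.1 * df.age
        res = fit_linear(df, "y")
        assert res[FRAIL_TERM].estimate == pytest.approx(0.5, abs=1e-10)
        assert res[FRAIL_TERM].p_value < 1e-12

    def test_matches_normal_equations_oracle(self):
        df = _toy_df(6, seed=2)
        rng = np.random.default_rng(3)
        df["y"] = rng.normal(size=6)
        res = fit_linear(df, "y")
        X = np.column_stack(
            [
                np.ones(6),
                (df.group == "frail").astype(float),
                (df.group == "pre_frail").astype(float),
                df.age,
                df.sex,
            ]
        )
        beta = ols_normal_equations(X, df["y"].to_numpy())
        assert res[FRAIL_TERM].estimate == pytest.approx(beta[1], abs=1e-10)
        assert res[PREFRAIL_TERM].estimate == pytest.approx(beta[2], abs=1e-10)

    def test_ci_contains_estimate_and_n_counts_complete_rows(self):
        df = _toy_df(40, seed=4)
        rng = np.random.default_rng(5)
        df["y"] = rng.normal(size=40)
        df.loc[:4, "y"] = np.nan
        res = fit_linear(df, "y")
        r = res[FRAIL_TERM]
        assert r.ci_low <= r.estimate <= r.ci_high
        assert r.n == 35

    def test_rank_deficiency_reported(self):
        df = _toy_df(12, seed=6)
        df["age2"] = df["age"]  # exact duplicate covariate
        rng = np.random.default_rng(0)
        df["y"] = rng.normal(size=12)
        with pytest.raises(ValueError, match="rank deficient"):
            fit_linear(df, "y", covariates=("age", "age2", "sex"))

    def test_empty_frail_group_omits_contrast(self):
        df = _toy_df(20, seed=7, groups=("pre_frail", "non_frail"))
        rng = np.random.default_rng(1)
        df["y"] = rng.normal(size=20)
        res = fit_linear(df, "y")
        assert FRAIL_TERM not in res and PREFRAIL_TERM in res


class TestLogisticFit:
    def test_two_by_two_equals_cross_ratio(self):
        # frail: 20 events / 30 non-events; non-frail: 10 / 40
        rows = (
            [("frail", 1)] * 20 + [("frail", 0)] * 30
            + [("non_frail", 1)] * 10 + [("non_frail", 0)] * 40
        )
        df = pd.DataFrame(rows, columns=["group", "lacunar_present"])
        res = fit_logistic(df, covariates=())
        assert res[FRAIL_TERM].estimate == pytest.approx(
            (20 * 40) / (30 * 10), abs=1e-6
        )

    def test_matches_grid_likelihood_oracle(self):
        # 10-row hand dataset with a binary covariate (well-conditioned MLE)
        df = pd.DataFrame(
            {
                "group": ["frail"] * 5 + ["non_frail"] * 5,
                "sex": [0, 1, 0, 1, 0, 1, 0, 1, 0, 1],
                "lacunar_present": [1, 1, 0, 1, 0, 0, 1, 0, 0, 1],
            }
        )
        res = fit_logistic(df, covariates=("sex",))
        X = np.column_stack(
            [np.ones(10), (df.group == "frail").astype(float), df.sex]
        )
        beta = logistic_mle_grid(X, df["lacunar_present"].to_numpy())
        assert np.log(res[FRAIL_TERM].estimate) == pytest.approx(beta[1], abs=1e-6)

    def test_null_association_gives_or_near_one(self):
        rng = np.random.default_rng(9)
        df = _toy_df(4000, seed=9)
        df["lacunar_present"] = rng.integers(0, 2, 4000)
        res = fit_logistic(df)
        assert res[FRAIL_TERM].estimate == pytest.approx(1.0, abs=0.25)

    def test_separation_flagged_not_fabricated(self):
        df = _toy_df(16, seed=10, groups=("frail", "non_frail"))
        df["lacunar_present"] = (df.group == "frail").astype(int)  # perfect split
        res = fit_logistic(df, covariates=())
        r = res[FRAIL_TERM]
        assert r.flag == "separation"
        assert r.ci_low is None and r.ci_high is None

    def test_single_class_outcome_rejected(self):
        df = _toy_df(10, seed=11)
        df["lacunar_present"] = 1
        with pytest.raises(ValueError, match="single class"):
            fit_logistic(df)


class TestSecondaryAndExploratory:
    def _volume_df(self, coupling, n=400, seed=12):
        df = generate_cohort(
            CohortSpec(volume_shape_coupling=coupling, seed=seed)
        )
        return df

    def test_fully_volume_mediated_effect_vanishes(self):
        rng = np.random.default_rng(13)
        df = _toy_df(300, seed=13)
        df["vol_total_ml"] = np.exp(
            rng.normal(0.4 * (df.group == "frail"), 0.5)
        )
        # shape outcome is a pure function of volume: no direct group effect
        df["shape"] = 1.0 + 0.2 * transform_volume(df["vol_total_ml"].to_numpy())
        out = fit_shape_secondary(df, "shape")
        assert abs(out[FRAIL_TERM]["adjusted"].estimate) < 1e-10

    def test_volume_independent_effect_unchanged(self):
        rng = np.random.default_rng(14)
        df = _toy_df(300, seed=14)
        df["vol_total_ml"] = np.exp(rng.normal(0, 0.5, 300))
        df["shape"] = 1.0 + 0.3 * (df.group == "frail") + rng.normal(0, 0.05, 300)
        out = fit_shape_secondary(df, "shape")
        b0 = out[FRAIL_TERM]["unadjusted"].estimate
        b1 = out[FRAIL_TERM]["adjusted"].estimate
        assert b1 == pytest.approx(b0, abs=0.02)

    def test_coupled_generation_attenuates(self):
        df = self._volume_df(coupling=0.3)
        out = fit_shape_secondary(df, "concavity_index_pvconf")
        for term in (FRAIL_TERM, PREFRAIL_TERM):
            assert abs(out[term]["adjusted"].estimate) < abs(
                out[term]["unadjusted"].estimate
            )

    def test_exploratory_exact_recovery_when_deterministic(self):
        df = _toy_df(40, seed=15)
        df["slowness"] = (np.arange(40) % 2).astype(int)
        df["y"] = 3.0 + 0.65 * df["slowness"] + 0.02 * df["age"]
        res = fit_component_exploratory(df, "y", "slowness")
        assert res.estimate == pytest.approx(0.65, abs=1e-10)

    def test_null_component_p_values_uniform(self):
        """With no generating effect, exploratory p-values are U(0,1)."""
        pvals = []
        for seed in range(250):
            df = generate_cohort(
                CohortSpec(
                    n_frail=20, n_prefrail=30, n_nonfrail=20,
                    beta_frail=0.0, beta_prefrail=0.0, beta_slowness=0.0,
                    seed=seed,
                )
            )
            res = fit_component_exploratory(
                df, "vol_total_ml", "weight_loss",
                covariates=("age", "sex", "icv_ml"), transform="ln100",
            )
            pvals.append(res.p_value)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_unknown_component_rejected(self):
        df = _toy_df(10)
        with pytest.raises(ValueError, match="component"):
            fit_component_exploratory(df, "age", "speediness")


class TestDemographics:
    def test_anova_matches_textbook_oracle(self):
        g1, g2, g3 = [1.0, 2.0, 3.0], [2.0, 3.5, 4.0], [5.0, 6.0, 7.5]
        df = pd.DataFrame(
            {
                "group": ["frail"] * 3 + ["pre_frail"] * 3 + ["non_frail"] * 3,
                "age": g1 + g2 + g3,
                "sex": [0, 1] * 4 + [0],
            }
        )
        table = demographics_table(df)
        p = table.loc[table.variable == "age", "p_value"].item()
        f = anova_f([np.array(g) for g in (g1, g2, g3)])
        expected = stats.f.sf(f, 2, 6)
        assert p == pytest.approx(expected, abs=1e-10)

    def test_chi2_matches_direct_formula(self):
        counts = {"frail": (12, 18), "pre_frail": (40, 45), "non_frail": (43, 12)}
        rows = []
        for g, (n0, n1) in counts.items():
            rows += [{"group": g, "age": 70.0, "sex": 0}] * n0
            rows += [{"group": g, "age": 70.0, "sex": 1}] * n1
        table = demographics_table(pd.DataFrame(rows))
        p = table.loc[table.variable == "sex", "p_value"].item()
        observed = np.array([list(v) for v in counts.values()])
        expected_p = stats.chi2.sf(chi2_statistic(observed), 2)
        assert p == pytest.approx(expected_p, abs=1e-10)

    def test_identical_constant_groups_boundary(self):
        df = pd.DataFrame(
            {
                "group": ["frail"] * 3 + ["non_frail"] * 3,
                "age": [70.0] * 6,
                "sex": [0, 1, 0, 1, 0, 1],
            }
        )
        table = demographics_table(df)
        assert table.loc[table.variable == "age", "p_value"].item() == 1.0

    def test_single_group_rejected(self):
        df = pd.DataFrame({"group": ["frail"] * 5, "age": range(5), "sex": [0] * 5})
        with pytest.raises(ValueError, match="two"):
            demographics_table(df)


class TestCorrelation:
    def _df(self, x, y):
        return pd.DataFrame({"vol_total_ml": np.exp(x) / 100.0, "gm_cbf": y})

    def test_perfect_linear(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        r, p, n = correlate_volume_perfusion(self._df(x, 2 * x + 1))
        assert r == pytest.approx(1.0)
        r, _, _ = correlate_volume_perfusion(self._df(x, -x))
        assert r == pytest.approx(-1.0)

    def test_matches_covariance_oracle(self):
        x = np.array([0.3, 1.1, 2.0, 2.5, 3.3])
        y = np.array([55.0, 62.0, 48.0, 71.0, 50.0])
        r, _, n = correlate_volume_perfusion(self._df(x, y))
        assert r == pytest.approx(pearson_r(x, y), abs=1e-12)
        assert n == 5

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError, match="3"):
            correlate_volume_perfusion(self._df(np.array([1.0, 2.0]), np.array([1.0, 2.0])))

    def test_zero_variance_rejected(self):
        x = np.array([1.0, 1.0, 1.0, 1.0])
        with pytest.raises(ValueError, match="variance"):
            correlate_volume_perfusion(self._df(x, np.array([1.0, 2.0, 3.0, 4.0])))


class TestPipeline:
    def test_end_to_end_deterministic_report(self, tmp_path):
        df = generate_cohort(CohortSpec(seed=21))
        res1 = run_pipeline(cohort=df, outdir=tmp_path / "a")
        res2 = run_pipeline(cohort=df, outdir=tmp_path / "b")
        assert res1.summary() == res2.summary()
        assert (tmp_path / "a" / "model_results.csv").exists()
        assert (tmp_path / "a" / "summary.txt").exists()

    def test_missing_columns_listed(self):
        with pytest.raises(ValueError, match="vol_total_ml"):
            run_pipeline(cohort=pd.DataFrame({"group": ["frail"], "age": [70]}))

    def test_empty_frail_group_handled(self):
        df = generate_cohort(CohortSpec(n_frail=0, seed=5))
        res = FrailtySVDModel(df).fit()
        vol = res.volume_models["vol_total_ml"]
        assert FRAIL_TERM not in vol and PREFRAIL_TERM in vol

    def test_exclusion_counts_consistent(self):
        df = generate_cohort(CohortSpec(seed=22))
        df.loc[:9, "gm_cbf"] = np.nan
        res = FrailtySVDModel(df).fit()
        for outcome, contrasts in res.perfusion_models.items():
            r = next(iter(contrasts.values()))
            assert r.n + res.exclusions[outcome] == len(df)
            complete = df[[outcome, "age", "sex"]].notna().all(axis=1).sum()
            assert r.n == complete
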