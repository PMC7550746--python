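import logging

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from wristband import mi_regression as mr
from wristband import preprocess as pp
from wristband import synthetic_cohort as sc


def small_spec(m=5, n_iter=3, seed=0):
    return mr.ImputationSpec(m=m, n_iter=n_iter, seed=seed)


def toy_frame(n=80, miss_frac=0.0, seed=0):
    rng = np.random.default_rng(seed)
    df = pd.DataFrame(
        {
            "x": rng.normal(10, 2, n),
            "g": rng.choice(["a", "b"], n),
            "h": rng.choice(["u", "v", "w"], n),
        }
    )
    if miss_frac:
        for c in df.columns:
            df.loc[rng.random(n) < miss_frac, c] = np.nan if c == "x" else pd.NA
    return df


class TestChainedImpute:
    def test_complete_data_passthrough(self):
        df = toy_frame()
        out = mr.chained_impute(df, small_spec())
        assert len(out) == 5
        for o in out:
            pd.testing.assert_frame_equal(o, df)

    def test_imputed_binary_cell_within_observed_levels(self):
        df = toy_frame(n=40, seed=1)
        df.loc[3, "g"] = pd.NA
        out = mr.chained_impute(df, small_spec())
        assert all(o.loc[3, "g"] in {"a", "b"} for o in out)
        # observed cells never altered
        for o in out:
            pd.testing.assert_series_equal(o["x"], df["x"])

    def test_imputations_differ_across_datasets(self):
        df = toy_frame(n=120, miss_frac=0.3, seed=2)
        out = mr.chained_impute(df, small_spec(m=6))
        filled = [tuple(o.loc[df["x"].isna(), "x"]) for o in out]
        assert len(set(filled)) > 1

    def test_excessive_missingness_refused(self):
        df = toy_frame(n=50)
        df.loc[df.index[:49], "x"] = np.nan
        with pytest.raises(ValueError, match="95%"):
            mr.chained_impute(df, small_spec())

    def test_mcar_continuous_calibration(self):
        # 20% MCAR on a N(10, 2) variable: pooled mean stays near truth
        rng = np.random.default_rng(7)
        n = 400
        df = pd.DataFrame(
            {"x": rng.normal(10, 2, n), "z": rng.normal(0, 1, n)}
        )
        df.loc[rng.random(n) < 0.2, "x"] = np.nan
        out = mr.chained_impute(df, small_spec(m=10, n_iter=5, seed=3))
        pooled_mean = np.mean([o["x"].mean() for o in out])
        mc_se = 2 / np.sqrt(n)
        assert abs(pooled_mean - 10.0) < 3 * mc_se


class TestFitLinear:
    def test_exact_fit(self):
        x = np.arange(10.0)
        design = pd.DataFrame({"Intercept": np.ones(10), "x": x})
        fit = mr.fit_linear(2 * x + 1, design)
        np.testing.assert_allclose(fit.params, [1.0, 2.0], atol=1e-10)
        assert fit.ssr == pytest.approx(0.0, abs=1e-16)

    def test_null_association(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, 2000)
        y = rng.permutation(x)
        design = pd.DataFrame({"Intercept": np.ones(2000), "x": x})
        fit = mr.fit_linear(y, design)
        assert abs(fit.params[1]) < 0.08

    def test_rank_deficiency_names_aliased_terms(self):
        x = np.arange(10.0)
        design = pd.DataFrame({"Intercept": np.ones(10), "x": x, "x2": 2 * x})
        with pytest.raises(ValueError, match="x2"):
            mr.fit_linear(x, design)

    def test_reference_levels_omitted(self):
        df = pd.DataFrame(
            {"season": ["fall", "winter", "spring", "summer"] * 3,
             "age_years": np.arange(12.0)}
        )
        X = mr.design_matrix(df, ["season", "age_years"])
        assert "season[fall]" not in X.columns
        assert {"season[winter]", "season[spring]", "season[summer]"} <= set(X.columns)


class TestPoolRubin:
    def test_identical_fits_have_zero_between_variance(self):
        x = np.arange(20.0)
        y = 3 * x + np.random.default_rng(1).normal(0, 1, 20)
        design = pd.DataFrame({"Intercept": np.ones(20), "x": x})
        fits = [mr.fit_linear(y, design) for _ in range(4)]
        pooled = mr.pool_rubin(fits)
        assert (pooled.table["B"] == 0).all()
        np.testing.assert_allclose(pooled.table["T"], pooled.table["W"])
        np.testing.assert_allclose(pooled.table["beta"], fits[0].params)

    def test_hand_computed_rubin_formulas(self):
        # two fits with betas 0 and 2, equal within-variance W0
        class Fake:
            def __init__(self, beta, var):
                self.params = np.array([beta])
                self._v = np.array([[var]])
                self.df_resid = 50
                self.term_names = ["x"]

            def cov_params(self):
                return self._v

        W0 = 0.5
        pooled = mr.pool_rubin([Fake(0.0, W0), Fake(2.0, W0)])
        row = pooled.table.iloc[0]
        assert row["beta"] == 1.0
        assert row["B"] == 2.0  # sample variance of {0, 2}
        assert row["W"] == W0
        assert row["T"] == W0 + (1 + 1 / 2) * 2.0
        lam = (1 + 0.5) * 2.0 / row["T"]
        df_old = (2 - 1) / lam**2
        df_obs = (50 + 1) / (50 + 3) * 50 * (1 - lam)
        df = 1 / (1 / df_old + 1 / df_obs)
        assert row["df"] == pytest.approx(df)
        half = stats.t.ppf(0.975, df) * np.sqrt(row["T"])
        assert row["ci_low"] == pytest.approx(1.0 - half)
        assert row["ci_high"] == pytest.approx(1.0 + half)

    def test_mismatched_terms_rejected(self):
        x = np.arange(12.0)
        d1 = pd.DataFrame({"Intercept": np.ones(12), "x": x})
        d2 = pd.DataFrame({"Intercept": np.ones(12), "z": x})
        f1, f2 = mr.fit_linear(x, d1), mr.fit_linear(x, d2)
        with pytest.raises(ValueError, match="mismatched"):
            mr.pool_rubin([f1, f2])


@pytest.fixture(scope="module")
def cohort():
    cfg = sc.default_config(seed=21)
    matrix, cov, records, truth = sc.simulate_cohort(cfg)
    filtered = pp.filter_by_detection(matrix)
    counts = pp.counts_per_wristband(matrix, records)
    std = pp.batch_standardize(filtered)
    return std, counts, cov


class TestModelSuite:

    def test_zero_missingness_equals_complete_data_fit(self, cohort):
        std, counts, cov = cohort
        complete = cov.data.copy().dropna()
        # restrict everything to complete cases so no imputation is needed
        keep = std.samples["participant_id"].isin(complete.index)
        from wristband.exposure_data import CovariateTable, ExposureMatrix

        sub_std = pp.StandardizedMatrix(
            std.values.loc[keep], std.samples.loc[keep],
            std.batch_medians, std.center, std.scale,
        )
        sub_counts = counts.loc[keep]
        suite = mr.run_model_suite(
            sub_std, sub_counts, CovariateTable(complete), small_spec(m=3, n_iter=1)
        )
        pooled = suite["total_detects"]
        # independent complete-data OLS
        samples = sub_std.samples.set_index("participant_id")
        frame = complete.copy()
        frame["season"] = samples.loc[frame.index, "season"]
        frame["gestational_age_start"] = samples.loc[frame.index, "gestational_age_start"]
        frame = frame.loc[sub_std.samples["participant_id"]]
        X = mr.design_matrix(frame, mr.TABLE_COVARIATES)
        y = sub_counts["total"].to_numpy(dtype=float)
        direct = mr.fit_linear(y, X)
        assert (pooled.table["B"] == 0).all()
        np.testing.assert_allclose(
            pooled.table["beta"].to_numpy(), np.asarray(direct.params), atol=1e-10
        )

    def test_absent_chemical_skipped_with_warning(self, cohort, caplog):
        std, counts, cov = cohort
        thin = pp.StandardizedMatrix(
            std.values[["Galaxolide", "Lilial"]], std.samples,
            std.batch_medians, std.center, std.scale,
        )
        with caplog.at_level(logging.WARNING, logger="wristband.mi_regression"):
            suite = mr.run_model_suite(thin, counts, cov, small_spec(m=2, n_iter=1))
        assert "nail_polish_use~Triphenyl phosphate" not in suite
        assert any("Triphenyl phosphate" in r.message for r in caplog.records)
        assert "total_detects" in suite

    def test_planted_effect_recovery_and_null_calibration(self):
        """Nail-polish effect recovered, null handwashing covered, over replicates."""
        # empirical truth: large-n complete-data coefficient on the
        # standardized scale implied by the planted log-scale effect
        base = sc.default_config(seed=0)
        big = sc.default_config(seed=99)
        big.n_participants = 20000
        big.missingness = {}
        matrix, cov, records, _ = sc.simulate_cohort(big)
        filtered = pp.filter_by_detection(matrix)
        assert "Diethyl phthalate" in filtered.chemical_ids
        std = pp.batch_standardize(filtered)
        samples = std.samples.set_index("participant_id")
        frame = cov.data.copy()
        frame["season"] = samples.loc[frame.index, "season"]
        frame["gestational_age_start"] = samples.loc[frame.index, "gestational_age_start"]
        X = mr.design_matrix(frame, mr.TABLE_COVARIATES + ["nail_polish_use"])
        y = std.values["Diethyl phthalate"].to_numpy()
        truth_beta = float(
            mr.fit_linear(y, X).params[list(X.columns).index("nail_polish_use[yes]")]
        )
        assert truth_beta > 0.05  # the planted log-shift is visible on the z scale

        cover_np = cover_hw = n_ok = 0
        reps = 20
        for r in range(reps):
            cfg = sc.default_config(seed=300 + r)
            m, cv, recs, _ = sc.simulate_cohort(cfg)
            f = pp.filter_by_detection(m)
            if "Diethyl phthalate" not in f.chemical_ids:
                continue  # below the screen in this replicate, model skipped
            n_ok += 1
            suite_std = pp.batch_standardize(f)
            counts = pp.counts_per_wristband(m, recs)
            suite = mr.run_model_suite(
                suite_std, counts, cv, small_spec(m=5, n_iter=3, seed=r)
            )
            lo, hi = suite["nail_polish_use~Diethyl phthalate"].ci("nail_polish_use[yes]")
            cover_np += lo <= truth_beta <= hi
            lo, hi = suite["handwashing_per_day~total"].ci("handwashing_per_day")
            cover_hw += lo <= 0.0 <= hi
        assert n_ok >= reps // 2
        assert cover_np >= int(0.8 * n_ok)
        assert cover_hw >= int(0.8 * n_ok)
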