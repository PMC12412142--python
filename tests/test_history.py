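"""History persistence, per-mass summaries, linear models, and drift."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from hramsst.history import (
    History,
    RankDeficiencyError,
    SSTRecord,
    append_record,
    batch_length_advisor,
    calibration_model_design,
    default_calibration_exclusion,
    drift_analysis,
    error_model_design,
    fit_calibration_model,
    fit_error_model,
    load_history,
    summarize_history,
)
from hramsst.simulate import SyntheticHistoryConfig, generate_history


def normal_equation_fit(y, X):
    """Independent OLS oracle: explicit normal equations + t-tests."""
    Xm = np.asarray(X, dtype=float)
    beta = np.linalg.solve(Xm.T @ Xm, Xm.T @ y)
    resid = y - Xm @ beta
    dof = len(y) - Xm.shape[1]
    sigma2 = resid @ resid / dof
    cov = sigma2 * np.linalg.inv(Xm.T @ Xm)
    se = np.sqrt(np.diag(cov))
    t = beta / se
    p = 2 * stats.t.sf(np.abs(t), dof)
    tss = np.sum((y - y.mean()) ** 2)
    r2 = 1 - resid @ resid / tss
    return beta, se, t, p, r2


def small_history(seed=0, **kwargs):
    defaults = dict(n_batches=12, replicates_per_phase=2, seed=seed)
    defaults.update(kwargs)
    history, truth = generate_history(SyntheticHistoryConfig(**defaults))
    return history, truth


def make_record(batch="B1", phase="PRE", replicate=1, **kwargs):
    defaults = dict(
        batch_id=batch,
        date="2024-05-01",
        polarity="POS",
        phase=phase,
        replicate=replicate,
        n_batch_injections=40,
        cal_type="CALMIX_FLEXMIX",
        cal_rms_ppm=0.12,
        days_since_cal=1.0,
        errors={"Caffeine": 0.5, "Verapamil": -0.2},
    )
    defaults.update(kwargs)
    return SSTRecord(**defaults)


class TestPersistence:
    def test_save_load_round_trip(self, tmp_path):
        history, _ = small_history()
        path = tmp_path / "history.csv"
        history.save(path)
        reloaded = load_history(path)
        pd.testing.assert_frame_equal(
            reloaded.df, history.df, check_dtype=False, check_exact=False, atol=1e-12
        )

    def test_append_preserves_uniqueness(self):
        history = append_record(History(), make_record())
        assert len(history) == 2  # one row per compound
        with pytest.raises(ValueError, match="duplicate"):
            append_record(history, make_record())

    def test_append_distinct_replicate_ok(self):
        history = append_record(History(), make_record(replicate=1))
        history = append_record(history, make_record(replicate=2))
        assert len(history) == 4

    def test_empty_file_with_header_loads_empty(self, tmp_path):
        path = tmp_path / "empty.csv"
        History().save(path)
        assert len(load_history(path)) == 0

    def test_schema_mismatch_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        pd.DataFrame({"foo": [1]}).to_csv(path, index=False)
        with pytest.raises(ValueError, match="missing columns"):
            load_history(path)

    def test_negative_covariates_rejected(self):
        with pytest.raises(ValueError):
            make_record(n_batch_injections=-1)

    def test_cal_quality_flag_threshold(self):
        assert make_record(cal_rms_ppm=0.3).cal_quality_flag == "GOOD"
        assert make_record(cal_rms_ppm=0.31).cal_quality_flag == "POOR"


class TestSummarizeHistory:
    def test_constant_errors_give_zero_sd(self):
        history = History()
        for batch in ("B1", "B2"):
            for phase in ("PRE", "POST"):
                for rep in (1, 2, 3):
                    history = append_record(
                        history,
                        make_record(
                            batch=batch, phase=phase, replicate=rep,
                            errors={"Caffeine": 1.0, "Verapamil": 1.0},
                        ),
                    )
        summary = summarize_history(history, k_injections=2, polarity="POS")
        assert np.allclose(summary.per_compound["mean_error"], 1.0)
        assert np.allclose(summary.per_compound["sd_error"], 0.0)
        assert summary.mean_of_means == pytest.approx(1.0)
        assert summary.sd_of_means == pytest.approx(0.0)

    def test_per_mass_means_recover_generator_truth(self, panel):
        mu = {c.name: 0.1 * i - 0.5 for i, c in enumerate(panel)}
        history, truth = small_history(
            seed=5, n_batches=40, replicates_per_phase=5, compound_true_means_ppm=mu
        )
        summary = summarize_history(history, k_injections=5, polarity="POS")
        for _, row in summary.per_compound.iterrows():
            se = row["sd_error"] / math.sqrt(row["n"])
            assert abs(row["mean_error"] - mu[row["compound"]]) < 3 * se + 1e-9

    def test_k2_same_expectation_larger_se(self):
        history, _ = small_history(seed=7, n_batches=40, replicates_per_phase=5)
        s5 = summarize_history(history, 5, "POS")
        s2 = summarize_history(history, 2, "POS")
        assert set(s2.per_compound["compound"]) == set(s5.per_compound["compound"])
        assert (s2.per_compound["n"] * 5 / 2 - s5.per_compound["n"]).abs().max() < 1e-9
        assert abs(s2.mean_of_means - s5.mean_of_means) < 0.2

    def test_first_k_means_lowest_replicate_indices(self):
        history = History()
        for rep, err in [(1, 0.0), (2, 0.0), (3, 100.0)]:
            history = append_record(
                history, make_record(replicate=rep, errors={"Caffeine": err})
            )
        summary = summarize_history(history, 2, "POS")
        assert summary.per_compound["mean_error"].iloc[0] == 0.0

    def test_aggregate_agrees_with_direct_recomputation(self):
        history, _ = small_history(seed=9)
        summary = summarize_history(history, 2, "POS")
        means = summary.per_compound["mean_error"].to_numpy()
        assert summary.mean_of_means == np.mean(means)
        assert summary.sd_of_means == np.std(means, ddof=1)

    def test_absent_polarity_rejected(self):
        history = append_record(History(), make_record())
        with pytest.raises(ValueError, match="NEG"):
            summarize_history(history, 2, "NEG")


class TestOlsOracle:
    @pytest.mark.parametrize("model", ["error", "calibration"])
    def test_matches_normal_equations_on_random_designs(self, model):
        """Both models agree with the explicit normal-equation oracle to
        1e-8 relative on 50 random small histories."""
        for seed in range(50):
            history, _ = small_history(
                seed=seed,
                n_batches=10,
                replicates_per_phase=2,
                drift_slope_ppm_per_injection=0.01 * (seed % 3),
                poor_cal_penalty_ppm=0.2,
                calmix_penalty_ppm=0.1,
                cal_quality_mix=0.5,
                calmix_fraction=0.5,
            )
            df = history.with_derived()
            if model == "error":
                sub = df[df["compound"] == "Caffeine"]
                y, X = error_model_design(sub)
                fit = fit_error_model(history, "Caffeine")
            else:
                sub = df[~default_calibration_exclusion(df)]
                y, X = calibration_model_design(sub)
                if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
                    continue  # degenerate random design (e.g. a single POOR batch)
                fit = fit_calibration_model(history)
            beta, se, t, p, r2 = normal_equation_fit(y, X)
            np.testing.assert_allclose(fit.estimates, beta, rtol=1e-8)
            np.testing.assert_allclose(fit.standard_errors, se, rtol=1e-8)
            np.testing.assert_allclose(fit.t_values, t, rtol=1e-8)
            np.testing.assert_allclose(fit.p_values, p, rtol=1e-8, atol=1e-300)
            assert fit.r_squared == pytest.approx(r2, rel=1e-8)

    def test_estimates_invariant_under_row_permutation(self):
        history, _ = small_history(seed=3, drift_slope_ppm_per_injection=0.02)
        fit1 = fit_error_model(history, "Caffeine")
        shuffled = History(
            history.df.sample(frac=1.0, random_state=1).reset_index(drop=True)
        )
        fit2 = fit_error_model(shuffled, "Caffeine")
        np.testing.assert_allclose(fit1.estimates, fit2.estimates, rtol=1e-12)


class TestErrorModel:
    def test_intercept_only_truth_recovered(self):
        history, _ = small_history(
            seed=21, n_batches=50, replicates_per_phase=2,
            compound_true_means_ppm={"Caffeine": 0.5},
            replicate_sd_pos=0.1,
        )
        fit = fit_error_model(history, "Caffeine")
        assert abs(fit.coef("Intercept") - 0.5) < 2 * fit.se("Intercept")

    def test_interaction_slope_recovered(self):
        history, truth = small_history(
            seed=22, n_batches=50, replicates_per_phase=5,
            drift_slope_ppm_per_injection=0.02,
        )
        fit = fit_error_model(history, "Caffeine")
        term = "phase_post:n_injections"
        assert abs(fit.coef(term) - 0.02) < 2 * fit.se(term)

    def test_max_hours_filters_long_batches(self):
        history, _ = small_history(seed=23, n_batches=60, injections_per_batch=(5, 120))
        full = fit_error_model(history, "Caffeine")
        short = fit_error_model(history, "Caffeine", max_hours=33.0)
        assert short.n_obs < full.n_obs
        df = history.with_derived()
        expected = ((df["compound"] == "Caffeine") & (df["batch_hours"] < 33.0)).sum()
        assert short.n_obs == expected

    def test_too_few_observations_rejected(self):
        history = append_record(History(), make_record())
        with pytest.raises(ValueError, match=">= 10"):
            fit_error_model(history, "Caffeine")


class TestCalibrationModel:
    def test_zero_noise_exact_fit(self):
        # constant base |error| of 0.5 for every compound + penalties:
        # the data follow the calibration model exactly, residuals vanish
        cfg = SyntheticHistoryConfig(
            n_batches=40, replicates_per_phase=2, seed=31,
            replicate_sd_pos=0.0, replicate_sd_neg=0.0,
            poor_cal_penalty_ppm=0.3, calmix_penalty_ppm=0.2,
            cal_quality_mix=0.5, calmix_fraction=0.5,
        )
        cfg.compound_true_means_ppm = {c.name: 0.5 for c in cfg.panel}
        history, _ = generate_history(cfg)
        fit = fit_calibration_model(history, exclusions=None)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-10)
        assert fit.coef("poor_cal") == pytest.approx(0.3, abs=1e-10)
        assert fit.coef("calmix_only") == pytest.approx(0.2, abs=1e-10)
        assert fit.coef("Intercept") == pytest.approx(0.5, abs=1e-10)

    def test_calmix_penalty_recovered(self):
        history, _ = small_history(
            seed=32, n_batches=50, replicates_per_phase=5,
            calmix_penalty_ppm=0.4, calmix_fraction=0.5, cal_quality_mix=0.3,
        )
        fit = fit_calibration_model(history)
        assert abs(fit.coef("calmix_only") - 0.4) < 2 * fit.se("calmix_only")

    def test_single_cal_type_rank_deficient(self):
        history, _ = small_history(seed=33, calmix_fraction=0.0, cal_quality_mix=0.5)
        with pytest.raises(RankDeficiencyError, match="calmix_only"):
            fit_calibration_model(history, exclusions=None)

    def test_default_exclusion_drops_stale_calmix(self):
        history, _ = small_history(
            seed=34, n_batches=60, calmix_fraction=0.5, cal_quality_mix=0.5,
            days_since_cal_max=14.0,
        )
        df = history.with_derived()
        excluded = default_calibration_exclusion(df)
        fit = fit_calibration_model(history)
        assert fit.n_obs == int((~excluded).sum())
        assert excluded.sum() > 0


class TestDriftAnalysis:
    def test_delta_is_post_minus_pre(self):
        history = History()
        for phase, err in (("PRE", 0.1), ("POST", 0.6)):
            for rep in (1, 2):
                history = append_record(
                    history,
                    make_record(phase=phase, replicate=rep, errors={"Caffeine": err}),
                )
        table, _ = drift_analysis(history)
        assert len(table) == 1
        assert table["delta_ppm"].iloc[0] == pytest.approx(0.5)

    def test_generated_drift_slope_reflected_in_delta(self):
        cfg = SyntheticHistoryConfig(
            n_batches=40, injections_per_batch=60, replicates_per_phase=5,
            drift_slope_ppm_per_injection=0.025, seed=41,
        )
        history, _ = generate_history(cfg)
        table, _ = drift_analysis(history)
        # E[delta] = slope * n = 0.025 * 60 = 1.5 ppm
        assert table["delta_ppm"].mean() == pytest.approx(1.5, abs=0.1)

    def test_zero_drift_centered_on_zero(self):
        history, _ = small_history(seed=42, n_batches=60, replicates_per_phase=5)
        table, _ = drift_analysis(history)
        n_points = len(table)
        assert abs(table["delta_ppm"].mean()) < 3 * table["delta_ppm"].std() / math.sqrt(n_points)

    def test_missing_phase_skipped_with_warning(self):
        history = append_record(History(), make_record(phase="PRE"))
        with pytest.warns(UserWarning, match="missing phase"):
            table, _ = drift_analysis(history)
        assert len(table) == 0

    def test_trend_slope_matches_generator(self):
        cfg = SyntheticHistoryConfig(
            n_batches=80, injections_per_batch=(10, 120), replicates_per_phase=5,
            drift_slope_ppm_per_injection=0.02, seed=43,
        )
        history, _ = generate_history(cfg)
        _, trends = drift_analysis(history)
        good = next(t for t in trends if t.stratum == "GOOD")
        # slope in ppm/hour = 0.02 ppm/injection * 3 injections/hour
        assert good.slope_ppm_per_hour == pytest.approx(0.06, abs=0.01)


class TestBatchLengthAdvisor:
    def test_below_limits_silent(self):
        assert batch_length_advisor(99) == []

    def test_over_hundred_injections_warns(self):
        notes = batch_length_advisor(101)
        assert len(notes) == 1 and "100 injections" in notes[0]

    def test_poor_calibration_twenty_hour_note(self):
        notes = batch_length_advisor(60, cal_quality_flag="POOR")
        assert len(notes) == 1 and "20 h" in notes[0]

    def test_good_calibration_no_twenty_hour_note(self):
        assert batch_length_advisor(60, cal_quality_flag="GOOD") == []

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            batch_length_advisor(-1)
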