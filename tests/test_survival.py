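"""Logistic survival fits, variance-pooled comparisons, recovery normalization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from poolselect.survival import (
    compare_median_survival,
    correlate_trait_with_survival,
    fit_all_replicates,
    fit_logistic_survival,
    logistic_survival,
    normalize_recovery,
)
from poolselect.synthetic import simulate_survival_assay

DAYS = list(range(1, 30, 2))  # every-other-day scoring


def exact_obs(t50, k, upper=1.0, plated=200, days=DAYS, strain="a", replicate="1"):
    p = logistic_survival(days, upper, k, t50)
    return pd.DataFrame(
        {
            "strain": strain,
            "replicate": replicate,
            "day": days,
            "plated": plated,
            "alive": np.round(p * plated).astype(int),
        }
    )


class TestFitLogisticSurvival:
    def test_recovers_exact_model_data(self):
        obs = exact_obs(t50=14.0, k=0.5, plated=100_000)
        fit = fit_logistic_survival(obs)
        assert fit.converged
        assert fit.t50 == pytest.approx(14.0, abs=1e-3)
        assert fit.steepness == pytest.approx(0.5, abs=1e-3)

    def test_all_alive_is_flagged_nonidentifiable(self):
        obs = pd.DataFrame(
            {
                "strain": "a",
                "replicate": "1",
                "day": [1, 7, 14],
                "plated": 100,
                "alive": 100,
            }
        )
        with pytest.warns(UserWarning, match="poorly identified"):
            fit = fit_logistic_survival(obs)
        assert not fit.converged

    def test_parameter_recovery_from_binomial_noise(self):
        # 20 simulated replicates at 500 worms/day recover t50=15 within a day
        recovered = []
        for seed in range(20):
            obs = simulate_survival_assay(
                [15.0], [0.5], days=DAYS, plated_per_day=500, seed=seed
            )
            fit = fit_logistic_survival(obs)
            assert fit.converged
            recovered.append(fit.t50)
        assert np.mean(recovered) == pytest.approx(15.0, abs=1.0)
        assert max(abs(t - 15.0) for t in recovered) < 2.0

    def test_fixed_upper_asymptote(self):
        obs = exact_obs(t50=12.0, k=0.8, upper=0.9, plated=100_000)
        fit = fit_logistic_survival(obs, upper=0.9)
        assert fit.upper == 0.9
        assert fit.t50 == pytest.approx(12.0, abs=0.01)

    def test_median_survival_invariant_to_common_plated_rescale(self):
        obs = simulate_survival_assay([14.0], [0.6], days=DAYS, plated_per_day=300, seed=4)
        scaled = obs.assign(plated=obs["plated"] * 3, alive=obs["alive"] * 3)
        f1 = fit_logistic_survival(obs)
        f2 = fit_logistic_survival(scaled)
        assert f1.t50 == pytest.approx(f2.t50, rel=1e-6)

    def test_predictions_bounded_by_asymptote(self):
        fit = fit_logistic_survival(exact_obs(t50=14.0, k=0.5))
        pred = logistic_survival(np.linspace(0, 40, 50), fit.upper, fit.steepness, fit.t50)
        assert np.all(pred > 0) and np.all(pred <= fit.upper + 1e-12)

    def test_requires_three_distinct_days(self):
        obs = exact_obs(t50=14.0, k=0.5, days=[10, 18])
        with pytest.raises(ValueError, match="3 distinct days"):
            fit_logistic_survival(obs)


class TestCompareMedianSurvival:
    def fits_frame(self, medians_by_strain):
        rows = []
        for strain, meds in medians_by_strain.items():
            for i, t50 in enumerate(meds, start=1):
                rows.append(
                    dict(
                        strain=strain,
                        replicate=str(i),
                        t50=float(t50),
                        steepness=0.5,
                        upper=1.0,
                        rss=0.0,
                        converged=True,
                        message="",
                    )
                )
        return pd.DataFrame(rows)

    def test_identical_replicate_medians_give_t_zero(self):
        fits = self.fits_frame({"a": [14, 15, 16], "b": [14, 15, 16]})
        res = compare_median_survival(fits)
        row = res.pairwise.iloc[0]
        assert row["t"] == 0.0 and row["pvalue"] == 1.0

    def test_matches_scipy_two_sample_t_when_only_two_strains(self):
        fits = self.fits_frame({"a": [14.1, 15.2, 15.9, 14.6], "b": [11.0, 12.4, 11.7, 12.1]})
        res = compare_median_survival(fits)
        expected = stats.ttest_ind(
            [14.1, 15.2, 15.9, 14.6], [11.0, 12.4, 11.7, 12.1], equal_var=True
        )
        row = res.pairwise.iloc[0]
        assert row["t"] == pytest.approx(expected.statistic)
        assert row["pvalue"] == pytest.approx(expected.pvalue)

    def test_pooled_df_spans_all_strains(self):
        fits = self.fits_frame({"a": [14, 15], "b": [11, 12], "c": [13, 13.5, 14.5]})
        res = compare_median_survival(fits)
        assert res.pooled_df == (2 - 1) + (2 - 1) + (3 - 1)

    def test_single_replicate_strain_excluded_with_warning(self):
        fits = self.fits_frame({"a": [14, 15], "b": [11, 12], "c": [13]})
        with pytest.warns(UserWarning, match="c"):
            res = compare_median_survival(fits)
        assert res.excluded == ["c"]

    def test_bartlett_type_i_error_near_nominal(self):
        # equal-variance normal medians: rejection rate ~5% at alpha=0.05
        rng = np.random.default_rng(2024)
        n_sim, rejections = 2000, 0
        for _ in range(n_sim):
            groups = [rng.normal(15.0, 1.0, size=4) for _ in range(6)]
            _, p = stats.bartlett(*groups)
            rejections += p < 0.05
        rate = rejections / n_sim
        assert 0.035 < rate < 0.065

    def test_separated_strains_detected_with_high_power(self):
        # t50 15 vs 10, 4 replicates each, binomial assay noise
        significant = 0
        n_seeds = 100
        for seed in range(n_seeds):
            obs = simulate_survival_assay(
                [15.0, 10.0],
                [0.5, 0.5],
                days=DAYS,
                plated_per_day=150,
                seed=seed,
                n_replicates=4,
                strains=["resistant", "sensitive"],
            )
            fits = fit_all_replicates(obs)
            res = compare_median_survival(fits)
            significant += res.pairwise["pvalue"].iloc[0] < 0.05
        assert significant >= 0.9 * n_seeds


class TestNormalizeRecovery:
    def test_eight_day_value_relative_to_one_day_mean(self):
        df = pd.DataFrame(
            {
                "strain": ["a"] * 3,
                "replicate": ["1", "2", "1"],
                "days_starved": [1, 1, 8],
                "assay": "brood_total",
                "value": [100.0, 100.0, 50.0],
            }
        )
        out = normalize_recovery(df)
        assert out.loc[out["days_starved"] == 8, "normalized_value"].iloc[0] == 0.5

    def test_identity_when_equal_to_baseline(self):
        df = pd.DataFrame(
            {
                "strain": ["a", "a"],
                "replicate": ["1", "1"],
                "days_starved": [1, 8],
                "assay": "body_length",
                "value": [750.0, 750.0],
            }
        )
        out = normalize_recovery(df)
        assert out["normalized_value"].iloc[1] == pytest.approx(1.0)

    @given(st.integers(0, 10_000))
    def test_one_day_normalized_mean_is_exactly_one(self, seed):
        rng = np.random.default_rng(seed)
        df = pd.DataFrame(
            {
                "strain": np.repeat(["a", "b"], 6),
                "replicate": list("123123") * 2,
                "days_starved": [1, 1, 1, 8, 8, 8] * 2,
                "assay": "brood_early",
                "value": rng.uniform(10, 300, size=12),
            }
        )
        out = normalize_recovery(df)
        day1 = out[out["days_starved"] == 1]
        means = day1.groupby("strain")["normalized_value"].mean()
        np.testing.assert_allclose(means, 1.0, rtol=1e-12)

    def test_zero_baseline_is_error(self):
        df = pd.DataFrame(
            {
                "strain": ["a", "a"],
                "replicate": ["1", "1"],
                "days_starved": [1, 8],
                "assay": "brood_total",
                "value": [0.0, 5.0],
            }
        )
        with pytest.raises(ValueError, match="zero"):
            normalize_recovery(df)


class TestTraitSurvivalCorrelation:
    def test_collinear_inputs_give_r2_one(self):
        traits = pd.DataFrame(
            {"strain": list("abcde"), "trait_value": [-2e-3, -1e-3, 0, 1e-3, 2e-3]}
        )
        fits = pd.DataFrame(
            {
                "strain": list("abcde"),
                "replicate": "1",
                "t50": [10.0, 12.0, 14.0, 16.0, 18.0],
                "converged": True,
            }
        )
        res = correlate_trait_with_survival(traits, fits)
        assert res.r_squared == pytest.approx(1.0)
        assert res.slope > 0

    def test_permutation_null_r2_matches_expectation(self):
        # under independence E[R^2] = 1 / (n - 1)
        n, n_perm = 8, 1000
        rng = np.random.default_rng(99)
        t50s = rng.normal(14, 2, size=n)
        traits_vals = rng.normal(0, 1e-3, size=n)
        strains = [f"s{i}" for i in range(n)]
        fits = pd.DataFrame(
            {"strain": strains, "replicate": "1", "t50": t50s, "converged": True}
        )
        r2s = []
        for _ in range(n_perm):
            traits = pd.DataFrame(
                {"strain": strains, "trait_value": rng.permutation(traits_vals)}
            )
            r2s.append(correlate_trait_with_survival(traits, fits).r_squared)
        assert np.mean(r2s) == pytest.approx(1 / (n - 1), abs=0.03)

    def test_end_to_end_simulation_with_strong_selection(self):
        # full chain: counts -> frequencies -> traits vs survival fits, with
        # pool dynamics and manual assay driven by the same mortality rates.
        # Strains share founder frequency and recovery weight so mortality is
        # the only fitness axis, and assay medians fall inside the scored
        # day range.
        from poolselect.frequency import infer_frequencies
        from poolselect.synthetic import (
            SimConfig,
            simulate_count_table,
            simulate_frequency_trajectories,
            simulate_panel,
        )
        from poolselect.traits import compute_trait_values
        from poolselect.variants import identify_unique_snvs

        n = 10
        mortality = np.linspace(0.02, 0.12, n)
        cfg = SimConfig(
            n_strains=n,
            seed=7,
            mortality_rates=mortality,
            recovery_weights=np.ones(n),
            initial_frequencies=np.full(n, 1 / n),
        )
        truth = simulate_frequency_trajectories(cfg)
        panel = simulate_panel(n, truth.config.unique_snv_counts, seed=7)
        snv_map = identify_unique_snvs(panel)
        counts = simulate_count_table(truth).filter_unique(snv_map)
        traits = compute_trait_values(infer_frequencies(snv_map, counts))[
            ["strain", "trait_value"]
        ]
        t50 = 25.0 - 120.0 * mortality  # hardy strains survive ~3x longer
        obs = simulate_survival_assay(
            t50,
            np.full(n, 0.5),
            days=DAYS,
            plated_per_day=300,
            seed=1,
            n_replicates=2,
            strains=truth.strains,
        )
        fits = fit_all_replicates(obs)
        res = correlate_trait_with_survival(traits, fits[fits["converged"]])
        assert res.n_strains == n
        assert res.r_squared > 0.5

    def test_requires_three_common_strains(self):
        traits = pd.DataFrame({"strain": ["a", "b"], "trait_value": [0.0, 1.0]})
        fits = pd.DataFrame(
            {"strain": ["a", "b"], "replicate": "1", "t50": [10.0, 12.0], "converged": True}
        )
        with pytest.raises(ValueError, match=">= 3"):
            correlate_trait_with_survival(traits, fits)
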