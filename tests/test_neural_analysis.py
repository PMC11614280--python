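"""Spike-count windowing, regressions, model comparison and permutations."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from rewardbases.neural_analysis import (
    ConditionTable,
    DegenerateFitError,
    SpikeDataset,
    WindowSpec,
    baseline_corrected_response,
    compare_models_ic,
    count_in_window,
    fit_basis_regression,
    fit_value_identity_regression,
    model_recovery,
    shuffle_interaction_count,
    shuffle_response_correlation,
    smoothed_rate,
    split_half_stability,
)
from rewardbases.synthetic_spikes import GeneratorConfig, generate


class TestWindowing:
    def test_empty_train(self):
        assert count_in_window([], (0.15, 0.5)) == 0

    def test_half_open_boundaries(self):
        # 0.5 excluded, 0.15 included
        assert count_in_window([0.1, 0.2, 0.6], (0.15, 0.5)) == 1
        assert count_in_window([0.15, 0.5], (0.15, 0.5)) == 1

    def test_rate_uses_window_size(self):
        spec = WindowSpec()
        spikes = [0.2, 0.25, 0.3, 0.35, 0.45]  # 5 spikes in 0.35 s, none before
        assert baseline_corrected_response(spikes, spec) == pytest.approx(
            5 / 0.35
        )

    def test_baseline_correction_sign(self):
        spec = WindowSpec()
        # suppression: 0 response spikes, 5 baseline spikes in 0.5 s
        spikes = [-0.4, -0.3, -0.25, -0.2, -0.1]
        assert baseline_corrected_response(spikes, spec) == pytest.approx(-10.0)

    def test_identical_rates_cancel(self):
        spec = WindowSpec(response=(0.0, 0.5), baseline=(-0.5, 0.0))
        spikes = [-0.25, 0.25]
        assert baseline_corrected_response(spikes, spec) == 0.0

    def test_smoothed_rate_constant_train(self):
        # deterministic 10 Hz grid: every 200 ms window holds exactly 2 spikes
        spikes = np.arange(0.05, 1.0, 0.1)
        out = smoothed_rate(spikes, trange=(0.0, 1.0))
        np.testing.assert_allclose(out["rate"], 10.0)

    def test_smoothed_rate_empty(self):
        out = smoothed_rate([], trange=(-0.5, 1.0))
        assert (out["rate"] == 0.0).all()

    def test_smoothed_rate_matches_bruteforce(self, rng):
        spikes = np.sort(rng.uniform(-0.5, 1.0, size=200))
        out = smoothed_rate(spikes, trange=(-0.5, 1.0))
        for t, rate in zip(out["t"], out["rate"]):
            brute = sum(1 for s in spikes if t <= s < t + 0.2)
            assert rate == pytest.approx(brute / 0.2)


class TestBasisRegression:
    def test_exact_recovery_on_noiseless_counts(self):
        # integer-valued forward model: counts = 2 + 4*r1 + 2*r2 exactly
        table = ConditionTable(
            pd.DataFrame(
                {
                    "reward_type": ["juice", "juice", "banana", "banana", "juice"],
                    "value": [1.0, 0.5, 0.5, 1.0, 0.25],
                },
                index=pd.Index(["a", "b", "c", "d", "e"], name="condition"),
            )
        )
        rng = np.random.default_rng(1)
        rows = []
        trial = 0
        for cond in table.conditions:
            mu = 2 + 4 * table.df.loc[cond, "r1"] + 2 * table.df.loc[cond, "r2"]
            assert mu == round(mu)
            for _ in range(3):
                rows.append(
                    ("n0", trial, cond, tuple(rng.uniform(0.15, 0.4999, int(mu))))
                )
                trial += 1
        ds = SpikeDataset(
            pd.DataFrame(
                rows, columns=["neuron_id", "trial_id", "condition", "spike_times"]
            )
        )
        fit = fit_basis_regression(ds, "n0", table)
        assert fit.params["r1"] == pytest.approx(4.0, abs=1e-10)
        assert fit.params["r2"] == pytest.approx(2.0, abs=1e-10)
        assert fit.params["const"] == pytest.approx(2.0, abs=1e-10)

    def test_requires_three_conditions(self, condition_table):
        rows = [
            ("n0", i, cond, (0.2, 0.3))
            for i, cond in enumerate(["j09", "b15", "j09", "b15"])
        ]
        ds = SpikeDataset(
            pd.DataFrame(
                rows, columns=["neuron_id", "trial_id", "condition", "spike_times"]
            )
        )
        with pytest.raises(DegenerateFitError):
            fit_basis_regression(ds, "n0", condition_table)

    def test_coverage_of_coefficient_estimates(self, condition_table):
        # planted b1, Gaussian count noise: the 2-SE interval should cover
        # the truth at roughly the nominal rate
        hits = 0
        reps = 300
        for s in range(reps):
            config = GeneratorConfig(
                n_neurons=1,
                trials_per_condition=40,
                b0=10.0,
                b1=3.0,
                b2=0.0,
                noise_sd=2.0,
                seed=20_000 + s,
            )
            ds = generate(config, condition_table)
            fit = fit_value_identity_regression(ds, "n000", condition_table)
            if abs(fit.params["value"] - 3.0) <= 2 * fit.bse["value"]:
                hits += 1
        assert hits / reps >= 0.93


class TestValueIdentityRegression:
    def test_coefficient_transform_exact(self, planted_dataset, condition_table):
        # b1 = (beta1+beta2)/2 and b2 = (beta1-beta2)/2 on every neuron
        for nid in planted_dataset.neurons:
            basis = fit_basis_regression(planted_dataset, nid, condition_table)
            vi = fit_value_identity_regression(planted_dataset, nid, condition_table)
            b1 = (basis.params["r1"] + basis.params["r2"]) / 2
            b2 = (basis.params["r1"] - basis.params["r2"]) / 2
            assert vi.params["value"] == pytest.approx(b1, abs=1e-10)
            assert vi.params["identity:value"] == pytest.approx(b2, abs=1e-10)
            np.testing.assert_allclose(
                vi.fittedvalues, basis.fittedvalues, atol=1e-10
            )

    def test_stimulus_model_fits_condition_means(self, planted_dataset, condition_table):
        nid = planted_dataset.neurons[0]
        fit = fit_value_identity_regression(
            planted_dataset, nid, condition_table, model="stimulus"
        )
        counts = planted_dataset.response_counts()
        sub = counts[counts["neuron_id"] == nid]
        for cond in condition_table.conditions:
            mean = sub.loc[sub["condition"] == cond, "count"].mean()
            assert fit.params[f"cond[{cond}]"] == pytest.approx(mean)

    def test_unknown_label_rejected(self, planted_dataset, condition_table):
        with pytest.raises(ValueError):
            fit_value_identity_regression(
                planted_dataset,
                planted_dataset.neurons[0],
                condition_table,
                model="value*identity",
            )

    def test_agrees_with_statsmodels(self, planted_dataset, condition_table):
        # independent cross-check of the least-squares engine
        nid = planted_dataset.neurons[2]
        fit = fit_value_identity_regression(planted_dataset, nid, condition_table)
        counts = planted_dataset.response_counts()
        sub = counts[counts["neuron_id"] == nid]
        reg = condition_table.regressors(list(sub["condition"]))
        X = sm.add_constant(
            np.column_stack(
                [
                    reg["value"].to_numpy(),
                    reg["value"].to_numpy() * reg["identity"].to_numpy(),
                ]
            ),
            prepend=False,
        )
        ref = sm.OLS(sub["count"].to_numpy(), X).fit()
        np.testing.assert_allclose(fit.params.to_numpy(), ref.params, atol=1e-10)
        np.testing.assert_allclose(fit.bse.to_numpy(), ref.bse, atol=1e-10)
        np.testing.assert_allclose(fit.pvalues.to_numpy(), ref.pvalues, atol=1e-10)

    def test_interaction_type_i_rate_near_nominal(self, condition_table):
        # value-only world: the interaction coefficient should reject at ~5%
        sig = tot = 0
        for s in range(25):
            ds = generate(
                GeneratorConfig.null(seed=30_000 + s), condition_table
            )
            for nid in ds.neurons:
                fit = fit_value_identity_regression(ds, nid, condition_table)
                sig += fit.pvalues["identity:value"] < 0.05
                tot += 1
        assert abs(sig / tot - 0.05) < 0.02


class TestModelComparison:
    def test_true_model_wins_on_planted_data(self, planted_dataset, condition_table):
        out = compare_models_ic(planted_dataset, condition_table, criterion="AIC")
        assert out.index[0] == "value+identity:value"

    def test_delta_aic_matches_statsmodels(self, planted_dataset, condition_table):
        # IC convention differs from statsmodels by an additive constant
        # per neuron; differences between models must agree exactly
        nid = planted_dataset.neurons[0]
        counts = planted_dataset.response_counts()
        sub = counts[counts["neuron_id"] == nid]
        reg = condition_table.regressors(list(sub["condition"]))
        y = sub["count"].to_numpy()
        R = reg["value"].to_numpy()
        IR = R * reg["identity"].to_numpy()
        X_small = sm.add_constant(R, prepend=False)
        X_big = sm.add_constant(np.column_stack([R, IR]), prepend=False)
        ref_delta = sm.OLS(y, X_big).fit().aic - sm.OLS(y, X_small).fit().aic
        mine_small = fit_value_identity_regression(
            planted_dataset, nid, condition_table, model="value"
        )
        mine_big = fit_value_identity_regression(
            planted_dataset, nid, condition_table, model="value+identity:value"
        )
        assert mine_big.aic - mine_small.aic == pytest.approx(ref_delta, abs=1e-8)

    def test_useless_regressor_increases_penalty(self, null_dataset, condition_table):
        nid = null_dataset.neurons[0]
        small = fit_value_identity_regression(
            null_dataset, nid, condition_table, model="value"
        )
        big = fit_value_identity_regression(
            null_dataset, nid, condition_table, model="value+identity+identity:value"
        )
        assert big.rss <= small.rss + 1e-9
        # the penalty part of the AIC grows by exactly 2 per extra coefficient
        n = big.n_obs
        penalty_big = big.aic - n * np.log(big.rss / n)
        penalty_small = small.aic - n * np.log(small.rss / n)
        assert penalty_big - penalty_small == pytest.approx(4.0)

    def test_bic_criterion_runs(self, planted_dataset, condition_table):
        out = compare_models_ic(planted_dataset, condition_table, criterion="BIC")
        assert set(out.columns) == {"BIC", "n_neurons"}
        assert out.index[0] == "value+identity:value"


class TestShuffleResponseCorrelation:
    def test_anticorrelated_population_below_all_nulls(self, condition_table):
        ds = generate(GeneratorConfig.anticorrelated(seed=21), condition_table)
        res = shuffle_response_correlation(
            ds, reps=1000, rng=np.random.default_rng(0)
        )
        assert res.null.shape == (1000,)
        assert res.observed < res.null.min()
        assert res.p == 0.0
        assert res.p_corrected == pytest.approx(1 / 1001)

    def test_null_true_population_within_null_band(self, condition_table):
        # per-neuron heterogeneity but identical selectivity: the observed
        # correlation behaves like a draw from the resampling null
        config = GeneratorConfig(
            b0=np.linspace(4.0, 16.0, 19), b1=3.0, b2=0.0, seed=22
        )
        ds = generate(config, condition_table)
        res = shuffle_response_correlation(
            ds, reps=1000, rng=np.random.default_rng(1)
        )
        lo, hi = np.quantile(res.null, [0.025, 0.975])
        assert lo <= res.observed <= hi


class TestShuffleInteractionCount:
    def test_planted_population_exceeds_all_nulls(self, planted_dataset, condition_table):
        res = shuffle_interaction_count(
            planted_dataset, condition_table, reps=1000, rng=np.random.default_rng(2)
        )
        assert res.observed >= 7
        assert res.observed > res.null.max()
        assert res.p == 0.0

    def test_null_population_count_near_binomial_mean(self, null_dataset, condition_table):
        res = shuffle_interaction_count(
            null_dataset, condition_table, reps=200, rng=np.random.default_rng(3)
        )
        # expectation 19 * 0.05 ~ 1; allow generous Monte-Carlo slack
        assert res.observed <= 5
        assert abs(res.null.mean() - 19 * 0.05) < 1.0


class TestModelRecovery:
    def test_generating_model_wins_with_separation(self, condition_table):
        ds = generate(GeneratorConfig.stimulus_selective(seed=23), condition_table)
        res = model_recovery(
            ds, condition_table, n_surrogates=300, rng=np.random.default_rng(4)
        )
        d_vi = res.delta_aic["value+identity:value"]
        d_st = res.delta_aic["stimulus"]
        assert d_vi.shape == (300,) and d_st.shape == (300,)
        # surrogates from the interaction model favour it (positive delta),
        # surrogates from the stimulus model favour stimulus (negative delta)
        assert np.mean(d_vi > 0) > 0.95
        assert np.mean(d_st < 0) > 0.95
        assert res.overlap < 0.05


class TestSplitHalf:
    def test_duplicated_trials_give_perfect_correlation(self, condition_table):
        base = generate(
            GeneratorConfig.planted(n_neurons=10, seed=24), condition_table
        )
        dup = base.df.copy()
        dup["trial_id"] = dup["trial_id"] + base.df["trial_id"].max() + 1
        ds = SpikeDataset(pd.concat([base.df, dup], ignore_index=True))
        s1, s2, r, p = split_half_stability(ds, condition_table)
        np.testing.assert_allclose(s1.to_numpy(), s2.to_numpy(), atol=1e-10)
        assert r == pytest.approx(1.0)

    def test_stationary_planted_effects_are_stable(self, planted_dataset, condition_table):
        s1, s2, r, p = split_half_stability(planted_dataset, condition_table)
        assert r > 0.5
        assert p < 0.01

    def test_null_population_uncorrelated(self, condition_table):
        rs = []
        for s in range(10):
            ds = generate(GeneratorConfig.null(seed=40_000 + s), condition_table)
            _, _, r, _ = split_half_stability(ds, condition_table)
            rs.append(r)
        assert abs(np.mean(rs)) < 0.25


class TestSpikeDatasetIO:
    def test_csv_roundtrip(self, planted_dataset, tmp_path):
        path = tmp_path / "spikes.csv"
        planted_dataset.to_csv(path)
        back = SpikeDataset.from_csv(path)
        assert list(back.df["condition"]) == list(planted_dataset.df["condition"])
        for a, b in zip(back.df["spike_times"], planted_dataset.df["spike_times"]):
            np.testing.assert_allclose(a, b, atol=1e-6)

    def test_exploded_spike_count_conserved(self, planted_dataset):
        exploded = planted_dataset.to_exploded()
        total = sum(len(t) for t in planted_dataset.df["spike_times"])
        assert len(exploded) == total

    def test_condition_table_roundtrip(self, condition_table, tmp_path):
        path = tmp_path / "conditions.csv"
        condition_table.to_csv(path)
        back = ConditionTable.from_csv(path)
        pd.testing.assert_frame_equal(back.df, condition_table.df)
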