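"""Factorial ANOVA, paired t-tests, covariate and density-TF correlations."""

import numpy as np
import pandas as pd
import pytest

from graintrap.effects import (
    FactorBins,
    bin_covariates,
    covariate_correlations,
    density_tf_correlation,
    fourway_anova,
    paired_ttest,
)

import oracles
from conftest import make_records


class TestFactorBins:
    def test_edges_assign_left_closed(self):
        bins = FactorBins()
        labels, out = bins.temperature_bins(np.array([19.9, 20.0, 24.99, 25.0, 39.9]))
        assert list(labels) == ["0-20", "20-25", "20-25", "25-30", "30-40"]
        assert out == 0

    def test_out_of_range_goes_to_outer_bin(self):
        bins = FactorBins()
        labels, out = bins.humidity_bins(np.array([85.0, -3.0, 55.0]))
        assert list(labels) == ["70-80", "0-50", "50-60"]
        assert out == 2

    def test_bad_edges_rejected(self):
        with pytest.raises(ValueError):
            FactorBins(temperature_edges=(0, 0, 10))

    def test_bin_covariates_warns_on_out_of_range(self):
        df = make_records({}, humidity=92.0)
        with pytest.warns(UserWarning, match="outer bin"):
            bin_covariates(df)


class TestFourwayAnova:
    def test_design_degrees_of_freedom(self, default_sim):
        table = fourway_anova(default_sim)
        assert table.loc["Insect density", "DF"] == 2
        assert table.loc["Moisture content", "DF"] == 1
        n = len(default_sim)
        assert table["DF"].sum() == n - 1  # model + residual DF identity
        assert (table["F"].dropna() >= 0).all()

    def test_single_level_factor_dropped_with_warning(self):
        df = make_records({1: {("top", "center"): 3}})
        df2 = make_records({1: {("middle", "r1"): 5}}, bin_id="b2", mc=14.0)
        both = pd.concat([df, df2], ignore_index=True)
        with pytest.warns(UserWarning, match="single level"):
            table = fourway_anova(both)
        assert "Insect density" not in table.index
        assert "Moisture content" in table.index

    def test_two_level_toy_matches_hand_anova(self):
        # single two-level factor, 3+3 observations
        g1, g2 = [1.0, 2.0, 3.0], [4.0, 6.0, 8.0]
        df = make_records({}, days=1).iloc[:6].copy()
        df["count"] = [int(v) for v in g1 + g2]
        df["mc"] = [10.7] * 3 + [14.0] * 3
        # keep every other factor single-level so only MC is retained
        with pytest.warns(UserWarning):
            table = fourway_anova(df)
        f_oracle, df_b, df_w = oracles.oneway_anova_f([g1, g2])
        assert table.loc["Moisture content", "F"] == pytest.approx(f_oracle, abs=1e-10)
        assert table.loc["Moisture content", "DF"] == df_b
        assert table.loc["Error", "DF"] == df_w

    def test_null_calibration(self):
        # iid noise response: ~5% of factor tests reject at alpha=.05
        # (the acceptance suite runs the full 200-seed version)
        n_seeds = 100
        rejections = trials = 0
        for seed in range(n_seeds):
            r = np.random.default_rng(seed)
            n = 240
            df = pd.DataFrame(
                {
                    "density": r.choice([0.1, 1.0, 5.0], n),
                    "mc": r.choice([10.7, 14.0], n),
                    "temperature": r.uniform(15, 35, n),
                    "humidity": r.uniform(40, 75, n),
                    "count": r.normal(size=n),
                }
            )
            table = fourway_anova(df)
            ps = table.drop(index="Error")["p"]
            rejections += int((ps <= 0.05).sum())
            trials += len(ps)
        assert abs(rejections / trials - 0.05) <= 0.03

    def test_power_against_planted_mc_effect(self):
        # the planted moisture effect is isolated by holding the covariate
        # regimes equal across MC levels, so the factor is not collinear
        # with the humidity bins
        from graintrap.simulate import SimConfig, simulate_experiment

        hits = 0
        n_seeds = 20
        for seed in range(n_seeds):
            cfg = SimConfig(
                seed=seed,
                mc_effect={10.7: 1.0, 14.0: 4.0},
                rh_mean={10.7: 52.0, 14.0: 52.0},
                temp_base={10.7: 26.0, 14.0: 26.0},
            )
            table = fourway_anova(simulate_experiment(cfg))
            hits += int(table.loc["Moisture content", "p"] < 0.001)
        assert hits >= 0.95 * n_seeds


class TestPairedTTest:
    def test_symmetric_differences_t_zero(self):
        t, p = paired_ttest([1.0, 2.0], [0.0, 3.0])  # d = (+1, -1)
        assert t == pytest.approx(0.0, abs=1e-12)

    def test_constant_shift_undefined(self):
        t, p = paired_ttest([1.0, 2.0, 3.0], [3.0, 4.0, 5.0])
        assert np.isnan(t) and np.isnan(p)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            paired_ttest([1.0, 2.0], [1.0])

    def test_matches_formula_oracle(self, rng):
        for _ in range(200):
            x = rng.normal(size=5)
            y = rng.normal(size=5)
            t, p = paired_ttest(x, y)
            assert t == pytest.approx(oracles.paired_t(list(x), list(y)), abs=1e-10)
            assert 0 <= p <= 1


class TestCovariateCorrelations:
    def test_exact_linear_function(self):
        df = make_records({}, days=5)
        # temperatures in exact half-degrees so 2*T is integral and the
        # count is an exact linear function of temperature
        df["temperature"] = 20.0 + 0.5 * (np.arange(len(df)) % 20)
        df["count"] = (2 * df["temperature"]).astype(int)
        out = covariate_correlations(df)
        assert out.loc[0, "r_count_temperature"] == pytest.approx(1.0, abs=1e-6)

    def test_zero_variance_flagged(self):
        df = make_records({})  # constant covariates, zero counts
        out = covariate_correlations(df)
        assert np.isnan(out.loc[0, "r_count_temperature"])

    def test_matches_oracle_on_toy_table(self, rng):
        df = make_records({}, days=1).iloc[:5].copy()
        df["count"] = rng.integers(0, 9, 5)
        df["temperature"] = rng.uniform(20, 30, 5)
        df["humidity"] = rng.uniform(40, 70, 5)
        out = covariate_correlations(df)
        r = oracles.pearson_r(list(df["count"]), list(df["temperature"]))
        assert out.loc[0, "r_count_temperature"] == pytest.approx(r, abs=1e-12)

    def test_independent_data_near_zero(self):
        rs = []
        for seed in range(30):
            r = np.random.default_rng(seed)
            df = make_records({}, days=10)
            df["count"] = r.poisson(3, len(df))
            df["temperature"] = r.uniform(20, 30, len(df))
            out = covariate_correlations(df)
            rs.append(out.loc[0, "r_count_temperature"])
        assert abs(np.mean(rs)) < 0.05


class TestDensityTF:
    def _three_phase_records(self, tf_map):
        frames = []
        for density in (0.1, 1.0, 5.0):
            per_day = tf_map(density)
            frames.append(
                make_records(
                    {
                        d: {
                            (layer, pos): per_day
                            for layer in ("top", "middle", "bottom")
                            for pos in ("center", "r1", "r2", "r3", "r4")
                        }
                        for d in range(1, 11)
                    },
                    density=density,
                )
            )
        return pd.concat(frames, ignore_index=True)

    def test_tf_proportional_to_density_r_one(self):
        df = self._three_phase_records(lambda d: int(10 * d))
        res = density_tf_correlation(df)
        defined = res.per_location.dropna(subset=["r"])
        assert np.allclose(defined["r"], 1.0)

    def test_single_phase_rejected(self):
        df = make_records({})
        with pytest.raises(ValueError):
            density_tf_correlation(df)

    def test_relabeling_locations_invariant(self, default_sim):
        res = density_tf_correlation(default_sim)
        swapped = default_sim.copy()
        swapped["position"] = swapped["position"].map(
            {"center": "r1", "r1": "center", "r2": "r2", "r3": "r3", "r4": "r4"}
        )
        res2 = density_tf_correlation(swapped)
        pd.testing.assert_frame_equal(
            res.window_means, res2.window_means, check_exact=False, atol=1e-12
        )

    def test_shuffled_tf_near_zero(self):
        # destroy the density-TF link by shuffling counts across phases
        rs = []
        for seed in range(25):
            r = np.random.default_rng(seed)
            df = self._three_phase_records(lambda d: 1)
            df["count"] = r.permutation(r.poisson(2, len(df)))
            res = density_tf_correlation(df, by_mc=False)
            rs.append(res.window_means["mean_r"].mean())
        assert abs(np.nanmean(rs)) < 0.1

    def test_ten_day_window_wins_on_default_design(self):
        from graintrap.simulate import SimConfig, simulate_experiment

        wins = 0
        n_seeds = 15
        for seed in range(n_seeds):
            rec = simulate_experiment(SimConfig(seed=seed))
            res = density_tf_correlation(rec)
            wins += int(res.overall_best_window == 10)
        assert wins > n_seeds / 2
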