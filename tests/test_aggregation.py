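"""Dispersion indices, Iwao/Taylor fits, and pattern classification."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from graintrap.aggregation import (
    AggregationAnalysis,
    classify_iwao,
    classify_taylor,
    iwao_fit,
    iwao_points,
    lloyd_index,
    taylor_fit,
)
from graintrap.core import SampleSet

import oracles


def _sets_from_counts(count_vectors, **meta):
    return [SampleSet(counts=tuple(int(x) for x in v), **meta) for v in count_vectors]


class TestLloydIndex:
    def test_constant_vector(self):
        assert lloyd_index([4] * 15) == pytest.approx(3.0)

    def test_poisson_identity(self):
        # when s2 == xbar the crowding equals the mean; verified on the
        # realized moments of an integer vector
        counts = np.array([1, 2, 3, 0, 2, 1, 2, 1, 2, 3, 1, 2, 2, 1, 1])
        il = lloyd_index(counts)
        m = counts.mean()
        s2 = counts.var(ddof=1)
        assert il == pytest.approx(m + s2 / m - 1)

    def test_hand_arithmetic_small_vector(self):
        # 4-element toy: mean 1.5, var 5/3 -> 1.5 + (5/3)/1.5 - 1
        assert lloyd_index([0, 1, 2, 3]) == pytest.approx(1.5 + (5 / 3) / 1.5 - 1)

    def test_zero_mean_undefined(self):
        assert math.isnan(lloyd_index([0] * 15))

    def test_matches_oracle_on_random_vectors(self, rng):
        for _ in range(1000):
            v = rng.integers(0, 20, size=15)
            if v.sum() == 0:
                continue
            assert lloyd_index(v) == pytest.approx(
                oracles.lloyd_crowding(list(map(float, v))), abs=1e-12
            )


class TestIwaoFit:
    def test_exact_line(self):
        pts = [(x, 2 + 3 * x) for x in (0.5, 1.0, 2.0, 4.0)]
        fit = iwao_fit(pts)
        assert fit.params[0] == pytest.approx(2.0, abs=1e-10)
        assert fit.params[1] == pytest.approx(3.0, abs=1e-10)

    def test_identity_line_poisson(self):
        pts = [(x, x) for x in (0.2, 1.0, 3.0)]
        fit = iwao_fit(pts)
        assert fit.params[0] == pytest.approx(0.0, abs=1e-10)
        assert fit.params[1] == pytest.approx(1.0, abs=1e-10)

    def test_matches_normal_equations_oracle(self, rng):
        for _ in range(200):
            x = rng.uniform(0.1, 10, size=5)
            y = rng.uniform(0, 20, size=5)
            fit = iwao_fit(list(zip(x, y)))
            b0, b1 = oracles.ols_line(list(x), list(y))
            assert fit.params[0] == pytest.approx(b0, abs=1e-10)
            assert fit.params[1] == pytest.approx(b1, abs=1e-10)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            iwao_fit([(1.0, 2.0)])
        with pytest.raises(ValueError):
            iwao_fit([(1.0, 2.0), (1.0, 3.0)])


class TestTaylorFit:
    def test_matches_ols_oracle_on_realized_moments(self):
        # the fit must agree exactly with an independent OLS on the
        # realized (ln mean, ln variance) points of integer count vectors
        vectors = [
            [0, 1, 0, 2, 1, 0, 1, 3, 0, 1, 0, 2, 1, 0, 1],
            [2, 4, 1, 5, 3, 2, 4, 6, 1, 3, 2, 5, 4, 2, 3],
            [5, 9, 3, 12, 7, 5, 8, 14, 2, 6, 4, 11, 9, 5, 7],
            [1, 1, 2, 1, 1, 1, 2, 1, 1, 2, 1, 1, 2, 1, 1],
        ]
        sets = _sets_from_counts(vectors)
        fit, excluded = taylor_fit(sets)
        xs = [math.log(s.mean) for s in sets]
        ys = [math.log(s.variance) for s in sets]
        lna, b = oracles.ols_line(xs, ys)
        assert excluded == 0
        assert fit.params[0] == pytest.approx(lna, abs=1e-10)
        assert fit.params[1] == pytest.approx(b, abs=1e-10)

    def test_zero_mean_and_zero_variance_sets_excluded(self):
        vectors = [
            [0] * 15,  # zero mean
            [3] * 15,  # zero variance
            [1, 2, 3, 0, 2, 1, 2, 1, 2, 3, 1, 2, 2, 1, 1],
            [2, 4, 1, 5, 3, 2, 4, 6, 1, 3, 2, 5, 4, 2, 3],
        ]
        fit, excluded = taylor_fit(_sets_from_counts(vectors))
        assert excluded == 2

    def test_too_few_usable_rejected(self):
        with pytest.raises(ValueError):
            taylor_fit(_sets_from_counts([[0] * 15, [1] * 15]))

    def test_parameter_recovery_negative_binomial(self, rng):
        # 200 sample sets, mu spanning one decade, k = 2: the fitted slope
        # approximates the analytic slope of ln(mu + mu^2/k) vs ln(mu)
        k = 2.0
        mus = np.geomspace(1.0, 10.0, 200)
        sets = []
        for mu in mus:
            p = k / (k + mu)
            sets.append(SampleSet(counts=tuple(rng.negative_binomial(k, p, 15))))
        fit, _ = taylor_fit(sets)
        lnmu = np.log(mus)
        lnvar = np.log(mus + mus**2 / k)
        analytic_slope = np.polyfit(lnmu, lnvar, 1)[0]
        assert abs(fit.params[1] - analytic_slope) < 0.1


class TestClassification:
    @pytest.mark.parametrize(
        "b0,b1,expected",
        [
            (0.07, -0.07, ("colony", "uniform")),
            (-0.36, 6.34, ("repulsion", "aggregated")),
            (-0.06, 2.99, ("repulsion", "aggregated")),
            (64.78, -38.50, ("colony", "uniform")),
            (-0.22, 1.20, ("repulsion", "aggregated")),
            (-2.51, 3.67, ("repulsion", "aggregated")),
        ],
    )
    def test_published_iwao_labels(self, b0, b1, expected):
        assert classify_iwao(b0, b1, tol=0.05) == expected

    @pytest.mark.parametrize(
        "b,expected",
        [(0.89, "uniform"), (1.55, "aggregated"), (1.26, "aggregated"),
         (-15.57, "uniform"), (1.08, "aggregated"), (2.18, "aggregated")],
    )
    def test_published_taylor_labels(self, b, expected):
        assert classify_taylor(b, tol=0.05) == expected

    def test_exact_boundary_identity(self):
        assert classify_iwao(0.0, 1.0, tol=1e-9) == ("individual", "random")
        assert classify_taylor(1.0, tol=1e-9) == "random"

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            classify_taylor(float("nan"))
        with pytest.raises(ValueError):
            classify_iwao(float("inf"), 1.0)

    @given(st.floats(min_value=-5, max_value=5), st.floats(min_value=0, max_value=1))
    @settings(deadline=None, max_examples=100)
    def test_monotone_in_slope(self, b, delta):
        # increasing b never moves the label back toward uniform
        order = {"uniform": 0, "random": 1, "aggregated": 2}
        assert order[classify_taylor(b + delta)] >= order[classify_taylor(b)]


class TestAnalysisObject:
    def test_poisson_data_classifies_random(self, rng):
        # 200 Poisson sample sets at mixed means -> slope ~ 1 -> "random"
        hits = 0
        n_seeds = 20
        for seed in range(n_seeds):
            r = np.random.default_rng(seed)
            sets = [
                SampleSet(counts=tuple(r.poisson(mu, 15)))
                for mu in r.uniform(1.0, 10.0, 200)
            ]
            fit, _ = taylor_fit(sets)
            if classify_taylor(fit.params[1], tol=0.1) == "random":
                hits += 1
        assert hits >= 0.9 * n_seeds

    def test_fit_reports_six_conditions(self, default_sim):
        res = AggregationAnalysis(default_sim).fit()
        assert len(res.reports) + len(res.failures) == 6
        frame = res.as_frame()
        assert {"b0", "b1", "lna", "b", "iwao_r2", "taylor_r2"} <= set(frame.columns)

    def test_pooled_and_per_replicate_modes(self, default_sim):
        per = AggregationAnalysis(default_sim).fit(mode="per-replicate")
        pooled = AggregationAnalysis(default_sim).fit(mode="pooled")
        assert all(r.n_replicates >= 2 for r in per.reports)
        assert all(r.n_replicates == 1 for r in pooled.reports)

    def test_exclusions_are_counted(self, default_sim):
        res = AggregationAnalysis(default_sim).fit()
        sets_total = len(AggregationAnalysis(default_sim).sample_sets)
        accounted = sum(r.n_points + r.n_excluded for r in res.reports)
        # failed conditions keep their sets out of the accounting
        assert accounted <= sets_total

    def test_summary_mentions_labels(self, default_sim):
        text = AggregationAnalysis(default_sim).fit().summary()
        assert "Taylor" in text and "aggregated" in text
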