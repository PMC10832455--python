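"""Prevalence curves, tail contrasts, and the delta-departure statistic."""

import numpy as np
import pandas as pd
import pytest

from pufa_phewas.canalization import (PrevalenceCurve, comparison_grid,
                                      delta_departure, delta_expected,
                                      delta_observed, dichotomize_by_mean,
                                      prevalence_by_percentile, tail_difference)


def _curve(prevs, n_per_bin=100):
    prevs = np.asarray(prevs, dtype=float)
    k = np.round(prevs * n_per_bin).astype(int)
    return PrevalenceCurve(pd.DataFrame({
        "bin": np.arange(1, len(prevs) + 1), "n": n_per_bin, "k": k,
        "prevalence": k / n_per_bin}))


class TestDichotomize:
    def test_split(self):
        assert dichotomize_by_mean([-1.0, 1.0]).tolist() == ["low", "high"]

    def test_mean_is_high_inclusive(self):
        labels = dichotomize_by_mean([0.0, 1.0, 2.0])  # mean = 1.0
        assert labels[1] == "high"

    def test_symmetric_split_is_balanced(self, rng):
        x = np.abs(rng.normal(size=500)) + 1e-6
        labels = dichotomize_by_mean(np.concatenate([x, -x]))  # exactly symmetric
        assert abs((labels == "high").sum() - 500) <= 1


class TestPrevalenceCurve:
    def test_counting_oracle_two_bins(self, rng):
        score = np.arange(200.0)
        status = (rng.random(200) < 0.3).astype(int)
        curve = prevalence_by_percentile(score, status, n_bins=2)
        t = curve.table
        assert t["k"].tolist() == [int(status[:100].sum()), int(status[100:].sum())]
        assert t["n"].tolist() == [100, 100]

    def test_constant_status_flat_curve(self):
        curve = prevalence_by_percentile(np.arange(300.0), np.ones(300), n_bins=100)
        assert (curve.table["prevalence"] == 1.0).all()

    def test_bin_sizes_near_equal_and_conserve(self, rng):
        score = rng.normal(size=1037)
        status = (rng.random(1037) < 0.2).astype(int)
        curve = prevalence_by_percentile(score, status, n_bins=100)
        t = curve.table
        assert t["n"].sum() == 1037
        assert t["n"].max() - t["n"].min() <= 1
        assert t["k"].sum() == status.sum()  # conservation of cases

    def test_monotone_transform_invariance(self, rng):
        score = rng.normal(size=500)
        status = (rng.random(500) < 0.3).astype(int)
        a = prevalence_by_percentile(score, status).table
        b = prevalence_by_percentile(np.exp(2.0 * score), status).table
        pd.testing.assert_frame_equal(a, b)

    def test_too_few_individuals(self):
        with pytest.raises(ValueError, match="need >="):
            prevalence_by_percentile(np.arange(50.0), np.zeros(50), n_bins=100)


class TestTails:
    def test_flat_curve_zero(self):
        assert tail_difference(_curve([0.2] * 100)) == pytest.approx(0.0)

    def test_monotone_curve_positive(self):
        assert tail_difference(_curve(np.linspace(0.0, 0.5, 100))) > 0

    def test_two_percent_means_two_bins(self):
        prevs = np.zeros(100)
        prevs[:2] = [0.10, 0.20]   # bottom two bins
        prevs[-2:] = [0.40, 0.60]  # top two bins
        assert tail_difference(_curve(prevs)) == pytest.approx(0.5 - 0.15)

    def test_delta_observed_sign_and_antisymmetry(self):
        a = _curve(np.linspace(0.0, 0.6, 100))
        b = _curve(np.linspace(0.0, 0.3, 100))
        d = delta_observed(a, b)
        assert d > 0
        assert delta_observed(b, a) == pytest.approx(-d)
        assert delta_observed(a, a) == pytest.approx(0.0)


class TestDeltaExpected:
    def test_seeded_determinism(self):
        a = _curve(np.linspace(0.05, 0.4, 100))
        b = _curve(np.linspace(0.05, 0.3, 100))
        e1 = delta_expected(a, b, n_iterations=10, seed=3)
        e2 = delta_expected(a, b, n_iterations=10, seed=3)
        np.testing.assert_array_equal(e1, e2)
        assert len(e1) == 10

    def test_self_consistency_on_model_generated_curves(self):
        """Curves drawn exactly from a logistic-in-percentile model: the mean
        expected delta matches the generative tail contrast."""
        rng = np.random.default_rng(5)
        x = np.arange(1, 101)
        pa = 1 / (1 + np.exp(-(-2.0 + 0.02 * x)))
        pb = 1 / (1 + np.exp(-(-2.0 + 0.01 * x)))
        n = 400
        a = PrevalenceCurve(pd.DataFrame({"bin": x, "n": n, "k": rng.binomial(n, pa),
                                          "prevalence": 0.0}))
        a.table["prevalence"] = a.table["k"] / n
        b = PrevalenceCurve(pd.DataFrame({"bin": x, "n": n, "k": rng.binomial(n, pb),
                                          "prevalence": 0.0}))
        b.table["prevalence"] = b.table["k"] / n
        exp = delta_expected(a, b, n_iterations=400, seed=7)
        true_delta = (pa[-2:].mean() - pa[:2].mean()) - (pb[-2:].mean() - pb[:2].mean())
        mc_se = exp.std(ddof=1) / np.sqrt(len(exp))
        # fitted-model mean tail contrast tracks the generative one
        assert abs(exp.mean() - true_delta) < 4 * mc_se + 0.01

    def test_empirical_sd_matches_binomial_propagation_oracle(self):
        """With known per-bin probabilities, var(delta) is the sum of the four
        case-weighted tail binomial variances."""
        x = np.arange(1, 101)
        pa = 1 / (1 + np.exp(-(-2.2 + 0.015 * x)))
        pb = 1 / (1 + np.exp(-(-2.2 + 0.008 * x)))
        n = 300
        a = PrevalenceCurve(pd.DataFrame({"bin": x, "n": n,
                                          "k": np.round(pa * n).astype(int),
                                          "prevalence": np.round(pa * n) / n}))
        b = PrevalenceCurve(pd.DataFrame({"bin": x, "n": n,
                                          "k": np.round(pb * n).astype(int),
                                          "prevalence": np.round(pb * n) / n}))
        exp = delta_expected(a, b, n_iterations=1000, seed=11)

        def tail_var(p, n_bin):
            lo = p[:2].mean(); hi = p[-2:].mean()
            return (hi * (1 - hi) + lo * (1 - lo)) / (2 * n_bin)

        oracle_sd = np.sqrt(tail_var(pa, n) + tail_var(pb, n))
        assert exp.std(ddof=1) == pytest.approx(oracle_sd, rel=0.10)

    def test_degenerate_group_rejected(self):
        a = _curve(np.zeros(100))
        with pytest.raises(ValueError, match="degenerate"):
            delta_expected(a, a, n_iterations=2, seed=0)


class TestDeltaDeparture:
    def test_zero_when_observed_matches_expectation(self):
        exp = np.array([0.1, 0.2, 0.3, 0.2])
        assert delta_departure(np.abs(exp).mean(), exp) == pytest.approx(0.0)

    def test_large_observed_deviation_is_negative(self):
        exp = np.array([0.01, 0.02, 0.015, 0.025])
        assert delta_departure(0.5, exp) < 0

    def test_small_observed_deviation_is_positive(self):
        exp = np.array([0.1, 0.12, 0.09, 0.11])
        assert delta_departure(0.0, exp) > 0

    def test_degenerate_spread_rejected(self):
        with pytest.raises(ValueError, match="zero spread"):
            delta_departure(0.1, np.array([0.2, 0.2]))


def test_comparison_grid_enumerates_each_once():
    grid = comparison_grid([f"d{i}" for i in range(5)], ["m1", "m2"])
    assert len(grid) == 5 * 2 * 2
    assert not grid.duplicated().any()
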