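"""MR estimators against independent oracles, harmonization rules,
outlier removal, and the protective-direction pipeline flags."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from pufa_phewas.mr import (MRConfig, egger, harmonize, ivw, remove_outliers,
                            run_mr, select_instruments, weighted_median)
from pufa_phewas.synthetic import SummaryStatsSpec, generate_summary_stats


def _input(bx, by, se_x=None, se_y=None):
    m = len(bx)
    return pd.DataFrame({
        "snp": [f"rs{i}" for i in range(m)],
        "beta_x": bx, "se_x": se_x if se_x is not None else [0.01] * m,
        "beta_y": by, "se_y": se_y if se_y is not None else [0.01] * m,
        "eaf": [0.3] * m,
    })


def _random_input(rng, m=10):
    bx = rng.normal(0.1, 0.05, m)
    bx[bx == 0] = 0.01
    return _input(bx, rng.normal(0.0, 0.05, m),
                  se_x=rng.uniform(0.005, 0.05, m), se_y=rng.uniform(0.005, 0.05, m))


class TestSelect:
    def test_threshold(self):
        tab = pd.DataFrame({"snp": ["a", "b"], "p": [1e-9, 1e-3]})
        assert len(select_instruments(tab)) == 1
        assert len(select_instruments(tab, p_threshold=1.0)) == 2

    def test_no_instruments_is_explicit(self):
        with pytest.raises(ValueError, match="no instruments"):
            select_instruments(pd.DataFrame({"snp": ["a"], "p": [0.5]}))

    def test_power_with_strong_instruments(self):
        """50 true instruments at n_exposure=100k: nearly all reach 5e-8."""
        ok = 0
        for s in range(100):
            e, _ = generate_summary_stats(
                SummaryStatsSpec(seed=20_000 + s, n_snps=50, n_exposure=100_000))
            ok += len(select_instruments(e)) >= 45
        assert ok >= 95


class TestHarmonize:
    def _tables(self, ea_y, oa_y, beta_y=0.3, eaf=0.3, ea_x="A", oa_x="G"):
        e = pd.DataFrame({"snp": ["rs1"], "effect_allele": [ea_x], "other_allele": [oa_x],
                          "eaf": [eaf], "beta": [0.1], "se": [0.01], "p": [1e-10], "n": [1000]})
        o = pd.DataFrame({"snp": ["rs1"], "effect_allele": [ea_y], "other_allele": [oa_y],
                          "eaf": [eaf], "beta": [beta_y], "se": [0.02], "p": [0.01], "n": [1000]})
        return e, o

    def test_identical_alleles_unchanged(self):
        h = harmonize(*self._tables("A", "G"))
        assert h["beta_y"].iloc[0] == pytest.approx(0.3)

    def test_swapped_alleles_flip_sign(self):
        h = harmonize(*self._tables("G", "A"))
        assert h["beta_y"].iloc[0] == pytest.approx(-0.3)

    def test_strand_complement_recognized(self):
        h = harmonize(*self._tables("T", "C"))  # complement of A/G
        assert h["beta_y"].iloc[0] == pytest.approx(0.3)

    def test_palindromic_ambiguous_dropped(self):
        e, o = self._tables("A", "T", eaf=0.5, ea_x="A", oa_x="T")
        with pytest.raises(ValueError, match="survive"):
            harmonize(e, o)

    def test_no_shared_snps(self):
        e, o = self._tables("A", "G")
        o = o.assign(snp=["rs2"])
        with pytest.raises(ValueError, match="shared"):
            harmonize(e, o)


class TestIVW:
    def test_identical_ratios(self):
        r = ivw(_input([0.2, 0.2], [0.1, 0.1]))
        assert r.estimate == pytest.approx(0.5)

    def test_exact_proportionality_zero_q(self):
        r = ivw(_input([1.0, 2.0], [0.5, 1.0]))
        assert r.estimate == pytest.approx(0.5)
        assert r.q_stat == pytest.approx(0.0, abs=1e-12)

    def test_matches_wls_through_origin_oracle(self, rng):
        for _ in range(100):
            inp = _random_input(rng)
            fit = sm.WLS(inp["beta_y"], inp[["beta_x"]],
                         weights=inp["se_y"] ** -2).fit()
            assert ivw(inp).estimate == pytest.approx(fit.params.iloc[0], abs=1e-10)

    def test_exposure_rescaling_equivariance(self, rng):
        inp = _random_input(rng)
        scaled = inp.assign(beta_x=2.0 * inp["beta_x"], se_x=2.0 * inp["se_x"])
        assert ivw(scaled).estimate == pytest.approx(ivw(inp).estimate / 2.0, abs=1e-12)

    def test_too_few_instruments(self):
        with pytest.raises(ValueError, match=">= 2"):
            ivw(_input([0.1], [0.1]))


def _wm_oracle(ratios, weights):
    """Direct summation: walk sorted ratios until half the weight is passed,
    interpolating between the straddling weight-centered positions."""
    order = np.argsort(ratios)
    r, w = np.asarray(ratios)[order], np.asarray(weights)[order] / np.sum(weights)
    below = 0.0
    for j in range(len(r)):
        center = below + w[j] / 2.0
        if center >= 0.5:
            if j == 0:
                return r[0]
            prev_center = below - w[j - 1] / 2.0
            frac = (0.5 - prev_center) / (center - prev_center)
            return r[j - 1] + frac * (r[j] - r[j - 1])
        below += w[j]
    return r[-1]


class TestWeightedMedian:
    def test_common_ratio(self):
        r = weighted_median(_input([0.1, 0.2, 0.4], [0.05, 0.1, 0.2]), n_boot=10)
        assert r.estimate == pytest.approx(0.5)

    def test_equal_weights_middle(self):
        inp = _input([1.0, 1.0, 1.0], [0.1, 0.5, 0.9])
        assert weighted_median(inp, n_boot=10).estimate == pytest.approx(0.5)

    def test_matches_cumulative_weight_oracle(self, rng):
        for _ in range(100):
            inp = _random_input(rng, m=int(rng.integers(3, 12)))
            got = weighted_median(inp, n_boot=2).estimate
            want = _wm_oracle(inp["beta_y"] / inp["beta_x"],
                              (inp["beta_x"] / inp["se_y"]) ** 2)
            assert got == pytest.approx(want, abs=1e-10)

    def test_instrument_order_and_sign_flip_invariance(self, rng):
        inp = _random_input(rng, m=7)
        base = weighted_median(inp, n_boot=2).estimate
        perm = inp.sample(frac=1.0, random_state=3).reset_index(drop=True)
        assert weighted_median(perm, n_boot=2).estimate == pytest.approx(base, abs=1e-12)
        flipped = inp.copy()
        flipped.loc[2, ["beta_x", "beta_y"]] *= -1.0
        assert weighted_median(flipped, n_boot=2).estimate == pytest.approx(base, abs=1e-12)

    def test_bootstrap_se_seeded(self):
        inp = _input([0.1, 0.12, 0.2, 0.15], [0.05, 0.01, 0.11, 0.04])
        a = weighted_median(inp, n_boot=200, seed=5)
        b = weighted_median(inp, n_boot=200, seed=5)
        assert a.se == b.se > 0

    def test_zero_beta_x_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            weighted_median(_input([0.0, 0.1, 0.2], [0.1, 0.1, 0.1]))


class TestEgger:
    def test_exact_line(self):
        bx = np.array([0.05, 0.1, 0.2, 0.3])
        slope, intercept = egger(_input(bx, 0.1 + 0.4 * bx))
        assert slope.estimate == pytest.approx(0.4, abs=1e-10)
        assert intercept.estimate == pytest.approx(0.1, abs=1e-10)

    def test_orients_exposure_positive(self):
        bx = np.array([0.05, -0.1, 0.2, -0.3])
        by = 0.1 + 0.4 * np.abs(bx)
        by[bx < 0] *= -1.0
        slope, intercept = egger(_input(bx, by))
        assert slope.estimate == pytest.approx(0.4, abs=1e-10)
        assert intercept.estimate == pytest.approx(0.1, abs=1e-10)


class TestOutlierRemoval:
    def test_homogeneous_untouched(self):
        inp = _input([0.1, 0.11, 0.12, 0.13, 0.14],
                     [0.05, 0.055, 0.06, 0.065, 0.07])
        out, removed = remove_outliers(inp)
        assert removed == [] and len(out) == 5

    def test_planted_outlier_removed(self, rng):
        bx = np.full(10, 0.1)
        by = 0.5 * bx + rng.normal(0, 0.002, 10)
        by[4] += 10 * 0.01  # 10-SD deviant ratio
        inp = _input(bx, by, se_y=[0.01] * 10)
        out, removed = remove_outliers(inp)
        assert removed == ["rs4"]
        assert len(out) == 9

    def test_removal_never_increases_q(self, rng):
        inp = _random_input(rng, m=12)
        q_before = ivw(inp).q_stat
        out, _ = remove_outliers(inp)
        assert ivw(out).q_stat <= q_before + 1e-12


class TestRunMr:
    def test_protective_filter_blocks_risk_effects(self):
        e, o = generate_summary_stats(SummaryStatsSpec(seed=31, causal_effect=0.3))
        rep = run_mr(e, o, MRConfig(n_boot=50))
        assert not rep["mr_supported"]

    def test_strong_protective_effect_supported(self):
        e, o = generate_summary_stats(SummaryStatsSpec(seed=32, causal_effect=-0.3))
        rep = run_mr(e, o, MRConfig(n_boot=50))
        assert rep["mr_supported"] and rep["dual_support"]
        assert rep["results"]["ivw"].or_ == pytest.approx(
            np.exp(rep["results"]["ivw"].estimate))

    def test_null_support_rate_near_one_sided_alpha(self):
        """causal=0: IVW p<0.05 with OR<1 in ~2.5% of replicates."""
        hits = sum(
            run_mr(*generate_summary_stats(
                SummaryStatsSpec(seed=40_000 + s, causal_effect=0.0)),
                MRConfig(n_boot=2, seed=s))["mr_supported"]
            for s in range(200))
        rate = hits / 200
        mc_se = np.sqrt(0.025 * 0.975 / 200)
        assert rate <= 0.025 + 3 * mc_se  # one-sided: must not over-reject
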