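"""Cohort preparation: median collapse, Z-scores, WHR, obesity classes,
case filter, allele-sum scoring."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pufa_phewas.prep import (classify_obesity, collapse_measurements,
                              compute_whr, min_case_filter, score_individuals,
                              zscore)


class TestCollapse:
    @pytest.mark.parametrize("values,flags,expected", [
        ([3.1], [0], 3.1),                      # singleton median
        ([1.0, 2.0, 9.0], [0, 0, 1], 1.5),      # flagged entry dropped first
        ([1.0, 2.0, 3.0], [0, 0, 0], 2.0),
    ])
    def test_examples(self, values, flags, expected):
        assert collapse_measurements(values, flags) == pytest.approx(expected)

    def test_all_flagged_is_missing(self):
        assert np.isnan(collapse_measurements([1.0], [1]))

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            collapse_measurements([1.0, 2.0], [0])

    @given(st.lists(st.tuples(st.floats(-1e6, 1e6), st.booleans()),
                    min_size=1, max_size=12),
           st.randoms(use_true_random=False))
    @settings(max_examples=60, derandomize=True)
    def test_permutation_invariant(self, pairs, rnd):
        shuffled = list(pairs)
        rnd.shuffle(shuffled)
        a = collapse_measurements([v for v, _ in pairs], [f for _, f in pairs])
        b = collapse_measurements([v for v, _ in shuffled], [f for _, f in shuffled])
        assert (np.isnan(a) and np.isnan(b)) or a == pytest.approx(b)


class TestZscore:
    def test_sample_sd_convention(self):
        z = zscore([1.0, 2.0, 3.0])
        assert z.iloc[2] == pytest.approx(1.0)  # sigma = sample SD = 1.0

    def test_value_at_mean_is_zero(self):
        assert zscore([4.0, 6.0, 5.0]).iloc[2] == pytest.approx(0.0)

    def test_normalization(self, rng):
        z = zscore(rng.gamma(2.0, 3.0, size=500))
        assert abs(z.mean()) < 1e-12
        assert abs(z.std(ddof=1) - 1.0) < 1e-12

    def test_missing_propagates(self):
        z = zscore([1.0, np.nan, 3.0])
        assert np.isnan(z.iloc[1]) and not np.isnan(z.iloc[0])

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            zscore([2.0, 2.0, 2.0])

    @given(st.floats(0.01, 100.0), st.floats(-50.0, 50.0))
    @settings(max_examples=40, derandomize=True)
    def test_affine_invariance(self, scale, shift):
        x = np.array([0.3, 1.7, 2.2, 5.9, 3.1])
        np.testing.assert_allclose(zscore(x), zscore(scale * x + shift), atol=1e-9)


class TestWhrAndObesity:
    def test_whr_examples(self):
        assert compute_whr(80.0, 100.0) == pytest.approx(0.8)
        assert compute_whr(95.0, 95.0) == pytest.approx(1.0)

    def test_nonpositive_hip(self):
        with pytest.raises(ValueError, match="hip"):
            compute_whr(80.0, 0.0)

    @pytest.mark.parametrize("measure,value,sex,status", [
        ("bmi", 30.0, "female", "non_obese"),   # boundary is non-obese
        ("bmi", 30.0001, "male", "obese"),
        ("whr", 0.86, "female", "obese"),
        ("whr", 0.86, "male", "non_obese"),
        ("whr", 0.95, "male", "non_obese"),
        ("whr", 0.951, "male", "obese"),
        ("whr", 0.85, "female", "non_obese"),
    ])
    def test_cutoffs(self, measure, value, sex, status):
        assert classify_obesity(measure, value, sex).status == status

    def test_unknown_inputs(self):
        with pytest.raises(ValueError, match="measure"):
            classify_obesity("height", 1.8, "male")
        with pytest.raises(ValueError, match="sex"):
            classify_obesity("whr", 0.9, "x")


class TestMinCaseFilter:
    def _cohort(self, cases: dict[str, int], n: int = 200) -> pd.DataFrame:
        df = pd.DataFrame({"id": range(n)})
        for code, k in cases.items():
            df[f"status_{code}"] = [1] * k + [0] * (n - k)
        return df

    def test_threshold_is_inclusive(self):
        kept = min_case_filter(self._cohort({"a": 49, "b": 50, "c": 0}))
        assert kept == ["b"]

    def test_configurable(self):
        kept = min_case_filter(self._cohort({"a": 5}), min_cases=5)
        assert kept == ["a"]


class TestScoring:
    def test_trivial_scores(self):
        dosages = pd.DataFrame({"rs1": [0.0, 2.0], "rs2": [0.0, 1.0]})
        weights = pd.DataFrame({"snp": ["rs1", "rs2"],
                                "effect_allele": ["A", "G"],
                                "weight": [0.5, -1.0]})
        s = score_individuals(dosages, weights)
        assert s.tolist() == [0.0, 2 * 0.5 + 1 * -1.0]

    def test_allele_flip_counts_effect_allele(self):
        dosages = pd.DataFrame({"rs1": [0.0, 1.0, 2.0]})
        weights = pd.DataFrame({"snp": ["rs1"], "effect_allele": ["A"], "weight": [0.5]})
        flipped = score_individuals(dosages, weights,
                                    dosage_effect_allele={"rs1": "G"},
                                    dosage_other_allele={"rs1": "G"})
        assert flipped.tolist() == [1.0, 0.5, 0.0]  # (2 - d) * w

    def test_unmatched_snp_raises(self):
        dosages = pd.DataFrame({"rs1": [1.0]})
        weights = pd.DataFrame({"snp": ["rs9"], "effect_allele": ["A"], "weight": [1.0]})
        with pytest.raises(KeyError, match="rs9"):
            score_individuals(dosages, weights)

    def test_chunked_by_chromosome_equals_single_pass(self, rng):
        """Additivity: per-chromosome scores summed equal the single pass."""
        snps = [f"rs{i}" for i in range(10)]
        dosages = pd.DataFrame(rng.uniform(0, 2, size=(20, 10)), columns=snps)
        weights = pd.DataFrame({"snp": snps, "effect_allele": "A",
                                "weight": rng.normal(size=10)})
        full = score_individuals(dosages, weights)
        chrom = np.array([1, 1, 1, 2, 2, 2, 2, 3, 3, 3])
        parts = sum(
            score_individuals(dosages[[s for s, c in zip(snps, chrom) if c == k]],
                              weights[chrom == k])
            for k in (1, 2, 3))
        np.testing.assert_allclose(full, parts, atol=1e-12)
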