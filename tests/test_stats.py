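import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats as sps

from mitoflux import (
    SamplerConfig,
    compact_letter_display,
    compare_groups,
    pearson_correlation,
    summarize_fluxes,
)
from mitoflux.sampling import FluxSampleSet

from .oracles import quantiles_sorted


def _sample_set(label, values, rxn="R"):
    arr = np.atleast_2d(np.asarray(values, dtype=float))
    return FluxSampleSet(label, [rxn], arr, SamplerConfig())


class TestSummaries:
    def test_constant_column(self):
        s = summarize_fluxes(_sample_set("d", [4.2] * 10))["R"]
        assert s.median == s.q1 == s.q3 == 4.2

    def test_small_sample_median(self):
        s = summarize_fluxes(_sample_set("d", [1, 2, 3, 4, 5]))["R"]
        assert s.median == 3 and s.q1 == 2 and s.q3 == 4

    def test_matches_independent_quantile_oracle(self):
        rng = np.random.default_rng(0)
        x = rng.gamma(2.0, 1.5, size=501)
        s = summarize_fluxes(_sample_set("d", x))["R"]
        q1, med, q3 = quantiles_sorted(x)
        assert (s.q1, s.median, s.q3) == pytest.approx((q1, med, q3), rel=1e-12)

    def test_unknown_reaction_rejected(self):
        with pytest.raises(KeyError, match="GHOST"):
            summarize_fluxes(_sample_set("d", [1, 2, 3]), ["GHOST"])


class TestCompactLetterDisplay:
    def test_all_same(self):
        letters = compact_letter_display(["a", "b", "c"], {})
        assert len(set(letters.values())) == 1

    def test_one_outlier_group(self):
        p = {("g1", "g3"): 0.001, ("g2", "g3"): 0.001, ("g1", "g2"): 0.9}
        letters = compact_letter_display(["g1", "g2", "g3"], p)
        assert letters["g1"] == letters["g2"]
        assert not set(letters["g3"]) & set(letters["g1"])

    def test_chain_structure(self):
        # g1 != g3 but g2 bridges both
        p = {("g1", "g3"): 0.01, ("g1", "g2"): 0.5, ("g2", "g3"): 0.5}
        letters = compact_letter_display(["g1", "g2", "g3"], p)
        assert set(letters["g1"]) & set(letters["g2"])
        assert set(letters["g2"]) & set(letters["g3"])
        assert not set(letters["g1"]) & set(letters["g3"])

    @given(st.integers(2, 6), st.integers(0, 10_000))
    def test_invariants_on_random_p_matrices(self, k, seed):
        rng = np.random.default_rng(seed)
        labels = [f"g{i}" for i in range(k)]
        p = {
            (labels[i], labels[j]): float(rng.uniform())
            for i in range(k) for j in range(i + 1, k)
        }
        letters = compact_letter_display(labels, p, alpha=0.05)
        assert all(letters[lab] for lab in labels)
        for (a, b), pv in p.items():
            shared = set(letters[a]) & set(letters[b])
            if pv < 0.05:
                assert not shared, (a, b, pv, letters)
            else:
                assert shared, (a, b, pv, letters)


class TestCompareGroups:
    def test_two_identical_constant_groups(self):
        comp = compare_groups(
            [_sample_set("d1", [2.0] * 5), _sample_set("d2", [2.0] * 5)], "R")
        assert comp.anova_p == 1.0
        assert comp.letters["d1"] == comp.letters["d2"]

    def test_constant_groups_with_different_means_differ(self):
        comp = compare_groups(
            [_sample_set("d1", [2.0] * 5), _sample_set("d2", [3.0] * 5)], "R")
        assert not set(comp.letters["d1"]) & set(comp.letters["d2"])

    def test_separated_group_gets_distinct_letter(self):
        rng = np.random.default_rng(1)
        sets = [
            _sample_set("g1", rng.normal(0, 1, 100)),
            _sample_set("g2", rng.normal(0, 1, 100)),
            _sample_set("g3", rng.normal(10, 1, 100)),
        ]
        comp = compare_groups(sets, "R")
        assert comp.anova_p < 1e-6
        assert set(comp.letters["g1"]) & set(comp.letters["g2"])
        assert not set(comp.letters["g3"]) & set(comp.letters["g1"])

    def test_two_group_anova_equals_t_squared(self):
        rng = np.random.default_rng(2)
        x, y = rng.normal(0, 1, 40), rng.normal(0.4, 1, 55)
        comp = compare_groups([_sample_set("a", x), _sample_set("b", y)], "R")
        t = sps.ttest_ind(x, y)
        assert comp.anova_F == pytest.approx(t.statistic**2, rel=1e-10)
        assert comp.anova_p == pytest.approx(t.pvalue, rel=1e-10)

    def test_tukey_kramer_supports_unequal_n(self):
        rng = np.random.default_rng(3)
        sets = [
            _sample_set("a", rng.normal(0, 1, 30)),
            _sample_set("b", rng.normal(0, 1, 80)),
            _sample_set("c", rng.normal(5, 1, 55)),
        ]
        comp = compare_groups(sets, "R")
        assert comp.tukey_pairwise[("a", "b")] > 0.05
        assert comp.tukey_pairwise[("a", "c")] < 0.05

    def test_single_group_rejected(self):
        with pytest.raises(ValueError, match="two"):
            compare_groups([_sample_set("a", [1, 2, 3])], "R")

    def test_thinning(self):
        rng = np.random.default_rng(4)
        sets = [_sample_set("a", rng.normal(0, 1, 100)),
                _sample_set("b", rng.normal(0, 1, 100))]
        comp = compare_groups(sets, "R", thin=10)
        assert comp is not None  # runs on the thinned series (n=10 each)


class TestPearson:
    def test_exact_positive_collinearity(self):
        x = np.arange(10.0)
        res = pearson_correlation(x, 2 * x + 1)
        assert res.r == 1.0

    def test_exact_negative_collinearity(self):
        x = np.arange(10.0)
        res = pearson_correlation(x, -x)
        assert res.r == -1.0

    def test_recovers_generating_correlation(self):
        rng = np.random.default_rng(8)
        cov = [[1, 0.6], [0.6, 1]]
        xy = rng.multivariate_normal([0, 0], cov, size=1000)
        res = pearson_correlation(xy[:, 0], xy[:, 1])
        assert res.ci95[0] < 0.6 < res.ci95[1]
        assert res.p < 1e-10

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            pearson_correlation([1, 1, 1], [1, 2, 3])

    def test_short_input_rejected(self):
        with pytest.raises(ValueError, match="three"):
            pearson_correlation([1, 2], [3, 4])
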