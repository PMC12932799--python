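"""Unit and property tests for the richness estimators."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import richgap as rg
from richgap.estimators import chao1_variance

from conftest import random_frequency_counts


def fc(s_obs, n, f):
    return rg.FrequencyCounts(s_obs=s_obs, n=n, f=f)


# ---------------------------------------------------------------- frequency


class TestFrequencyCounts:
    def test_small_example(self):
        out = rg.frequency_counts({"a": 1, "b": 1, "c": 2})
        assert (out.s_obs, out.n) == (3, 4)
        assert out.f == {1: 2, 2: 1}

    def test_label_invariance(self):
        a = rg.frequency_counts({"x": 3, "y": 1, "z": 2})
        b = rg.frequency_counts({"z": 2, "x": 3, "y": 1})
        assert a == b

    def test_empty_is_valid_degenerate(self):
        out = rg.frequency_counts([])
        assert (out.s_obs, out.n) == (0, 0)

    def test_rejects_zero_counts(self):
        with pytest.raises(ValueError):
            rg.frequency_counts([0, 1, 2])

    @given(st.lists(st.integers(min_value=1, max_value=50), min_size=1, max_size=100))
    @settings(deadline=None)
    def test_sufficient_statistic_identities(self, counts):
        out = rg.frequency_counts(counts)
        assert sum(out.f.values()) == out.s_obs == len(counts)
        assert sum(k * v for k, v in out.f.items()) == out.n == sum(counts)


# ---------------------------------------------------------------- chao1 / ichao1


class TestChao1:
    def test_no_singletons_gives_s_obs(self):
        assert rg.chao1(fc(3, 9, {3: 3})) == 3.0

    def test_hand_value_with_doubletons(self):
        # 10 + 4^2 / (2*2) = 14
        assert rg.chao1(fc(10, 4 + 4 + 12, {1: 4, 2: 2, 3: 4})) == 14.0

    def test_hand_value_bias_corrected_branch(self):
        # f2 = 0: 5 + 3*2/2 = 8
        assert rg.chao1(fc(5, 3 + 8, {1: 3, 4: 2})) == 8.0

    def test_variance_nonnegative_and_zero_without_singletons(self):
        assert chao1_variance(fc(3, 9, {3: 3})) == 0.0
        assert chao1_variance(fc(10, 24, {1: 4, 2: 2, 4: 4})) > 0


class TestIChao1:
    def test_no_tripletons_equals_chao1(self):
        x = fc(10, 24, {1: 4, 2: 2, 4: 4})
        assert rg.ichao1(x) == rg.chao1(x)

    def test_hand_value(self):
        # chao1 = 14; added term (2/(4*1)) * max(4 - 2*2/2, 0) = 0.5 * 2 = 1
        x = fc(10, 4 + 4 + 6 + 4 + 5, {1: 4, 2: 2, 3: 2, 4: 1, 5: 1})
        assert rg.ichao1(x) == pytest.approx(15.0)

    def test_f4_zero_substitution(self):
        # f4=0 -> use f4+1=1 in both places
        x = fc(8, 3 + 4 + 6 + 5, {1: 3, 2: 2, 3: 2, 5: 1})
        expected = rg.chao1(x) + (2 / 4.0) * max(3 - 2 * 2 / 2.0, 0)
        assert rg.ichao1(x) == pytest.approx(expected)

    def test_ordering_on_random_counts(self):
        rng = np.random.default_rng(0)
        for _ in range(500):
            x = random_frequency_counts(rng)
            assert x.s_obs <= rg.chao1(x) <= rg.ichao1(x)


# ---------------------------------------------------------------- rarefaction


class TestRarefactionExtrapolation:
    def test_two_singletons_at_m1(self):
        x = rg.frequency_counts([1, 1])
        assert rg.rarefaction_extrapolation(x, 1) == pytest.approx(1.0)

    def test_full_sample_returns_s_obs(self):
        x = rg.frequency_counts([1, 2, 3, 1])
        assert rg.rarefaction_extrapolation(x, x.n) == pytest.approx(x.s_obs)

    def test_limit_is_chao1(self):
        x = rg.frequency_counts([1, 1, 2, 2, 3, 5])
        assert rg.rarefaction_extrapolation(x, 10**7) == pytest.approx(
            rg.chao1(x), rel=1e-6
        )

    def test_interpolation_monotone_and_concave(self):
        rng = np.random.default_rng(3)
        counts = rng.geometric(0.3, size=30)
        x = rg.frequency_counts(counts)
        values = [rg.rarefaction_extrapolation(x, m) for m in range(x.n + 1)]
        diffs = np.diff(values)
        assert values[0] == 0.0
        assert values[1] == pytest.approx(1.0)
        assert np.all(diffs >= -1e-9)
        assert np.all(np.diff(diffs) <= 1e-9)

    def test_monte_carlo_oracle_single_assemblage(self):
        """Analytic interpolation equals the mean richness of random subsamples."""
        rng = np.random.default_rng(4)
        counts = rng.geometric(0.4, size=25)
        x = rg.frequency_counts(counts)
        n, m, reps = x.n, x.n // 2, 4000
        labels = np.repeat(np.arange(len(counts)), counts)
        richness = np.empty(reps)
        for r in range(reps):
            sub = rng.choice(labels, size=m, replace=False)
            richness[r] = np.unique(sub).size
        se = richness.std(ddof=1) / np.sqrt(reps)
        assert rg.rarefaction_extrapolation(x, m) == pytest.approx(
            richness.mean(), abs=3 * se + 1e-9
        )

    def test_no_singletons_extrapolation_flat(self):
        x = rg.frequency_counts([2, 3, 2])
        assert rg.rarefaction_extrapolation(x, 100) == 3.0


# ---------------------------------------------------------------- intervals


class TestChao1LogCI:
    def test_degenerate_without_singletons(self):
        x = rg.frequency_counts([2, 2, 3])
        assert rg.chao1_log_ci(x) == (3.0, 3.0)

    def test_brackets_point_estimate(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            x = random_frequency_counts(rng)
            lcl, ucl = rg.chao1_log_ci(x)
            assert x.s_obs <= lcl <= rg.chao1(x) + 1e-9
            assert rg.chao1(x) <= ucl + 1e-9


class TestBootstrapCI:
    @pytest.fixture(scope="class")
    def assemblage(self):
        rng = np.random.default_rng(6)
        return rg.AbundanceVector(
            region="AA",
            counts={f"s{i}": int(c) for i, c in enumerate(rng.geometric(0.3, size=40))},
        )

    def test_seeded_determinism(self, assemblage):
        a = rg.bootstrap_ci(assemblage, "ichao1", B=50, seed=9)
        b = rg.bootstrap_ci(assemblage, "ichao1", B=50, seed=9)
        assert a == b

    def test_interval_brackets_estimate(self, assemblage):
        fc_ = rg.frequency_counts(assemblage)
        lcl, ucl, se = rg.bootstrap_ci(assemblage, "chao1", B=100, seed=1)
        assert lcl <= rg.chao1(fc_) <= ucl
        assert se >= 0
        assert lcl >= fc_.s_obs

    def test_no_singletons_resamples_empirical_only(self):
        vec = rg.AbundanceVector(region="AA", counts={"a": 2, "b": 3, "c": 2})
        lcl, ucl, se = rg.bootstrap_ci(vec, "chao1", B=100, seed=2)
        assert lcl >= 3.0  # truncated at S_obs; no undetected mass added

    def test_rejects_tiny_B(self):
        vec = rg.AbundanceVector(region="AA", counts={"a": 2})
        with pytest.raises(ValueError):
            rg.bootstrap_ci(vec, "chao1", B=1)

    def test_sd_stable_in_B(self, assemblage):
        _, _, se_small = rg.bootstrap_ci(assemblage, "chao1", B=200, seed=3)
        _, _, se_big = rg.bootstrap_ci(assemblage, "chao1", B=2000, seed=4)
        assert se_small == pytest.approx(se_big, rel=0.25)
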