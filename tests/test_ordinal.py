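"""Ordinal symbolisation, permutation entropy, and complexity quantifiers."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ordinoise.ordinal import (
    ComplexityResult,
    OrdinalConfig,
    OrdinalDistribution,
    encode_pattern,
    jensen_shannon,
    ordinal_distribution,
    permutation_entropy,
    q0,
    statistical_complexity,
)


def brute_force_pattern(window, lag=1):
    """Independent oracle: stable argsort by (value, index), then lexicographic rank."""
    D = len(window)
    perm = tuple(sorted(range(D), key=lambda k: (window[k], k)))
    return sorted(itertools.permutations(range(D))).index(perm)


def brute_force_counts(x, D, lag=1):
    """Exhaustive window-by-window enumeration for small series."""
    counts = np.zeros(math.factorial(D), dtype=int)
    for i in range(len(x) - (D - 1) * lag):
        w = [x[i + j * lag] for j in range(D)]
        counts[brute_force_pattern(w)] += 1
    return counts


class TestEncodePattern:
    @pytest.mark.parametrize(
        "window,expected",
        [
            ((1, 2, 3), 0),  # identity permutation
            ((3, 2, 1), 5),  # full reversal
            ((1, 3, 2), 1),
            ((0.1, 0.4, 0.2, 0.9), 2),  # argsort (0,2,1,3)
        ],
    )
    def test_known_ranks(self, window, expected):
        assert encode_pattern(window) == expected

    def test_ties_break_earlier_index_first(self):
        # (2,2,1): the tied pair keeps temporal order, matching (2,3,1)
        assert encode_pattern((2, 2, 1)) == encode_pattern((2, 3, 1))
        assert encode_pattern((1, 1, 1)) == encode_pattern((1, 2, 3))

    @pytest.mark.parametrize("bad", [(1.0, np.nan, 2.0), (np.inf, 0.0, 1.0)])
    def test_rejects_non_finite(self, bad):
        with pytest.raises(ValueError, match="non-finite"):
            encode_pattern(bad)

    def test_rejects_scalar_window(self):
        with pytest.raises(ValueError):
            encode_pattern([1.0])

    @given(
        st.lists(st.integers(min_value=-5, max_value=5), min_size=2, max_size=5)
    )
    @settings(derandomize=True, max_examples=200)
    def test_matches_brute_force_oracle(self, window):
        assert encode_pattern(window) == brute_force_pattern(window)


class TestOrdinalDistribution:
    def test_window_count_and_normalisation(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=100)
        d = ordinal_distribution(x, OrdinalConfig(D=6))
        assert d.n_windows == 95
        assert d.counts.sum() == 95
        assert d.probabilities.sum() == pytest.approx(1.0, abs=1e-12)
        assert (d.probabilities >= 0).all()

    def test_d6_has_720_slots(self):
        d = ordinal_distribution(np.arange(100.0), OrdinalConfig(D=6))
        assert d.counts.shape == (720,)
        # strictly increasing series occupies exactly one pattern
        assert (d.counts > 0).sum() == 1
        assert d.counts.max() == 95

    def test_lagged_window_count(self):
        x = np.random.default_rng(1).normal(size=10)
        assert ordinal_distribution(x, OrdinalConfig(D=3, lag=1)).n_windows == 8
        assert ordinal_distribution(x, OrdinalConfig(D=3, lag=3)).n_windows == 4

    def test_too_short_series_names_minimum(self):
        with pytest.raises(ValueError, match="minimum length is 6"):
            ordinal_distribution(np.arange(5.0), OrdinalConfig(D=6))

    def test_rejects_non_finite_series(self):
        x = np.array([0.0, 1.0, np.nan, 2.0, 3.0, 4.0, 5.0])
        with pytest.raises(ValueError, match="non-finite"):
            ordinal_distribution(x, OrdinalConfig(D=3))

    @pytest.mark.parametrize("D,lag", [(2, 1), (3, 1), (3, 2), (4, 1)])
    def test_matches_exhaustive_enumeration(self, D, lag):
        rng = np.random.default_rng(42)
        for x in (rng.normal(size=12), rng.integers(0, 3, size=12).astype(float)):
            d = ordinal_distribution(x, OrdinalConfig(D=D, lag=lag))
            assert np.array_equal(d.counts, brute_force_counts(x, D, lag))

    @given(st.sampled_from(["exp", "cube", "affine"]), st.integers(0, 2**31 - 1))
    @settings(derandomize=True, max_examples=25, deadline=None)
    def test_invariant_under_monotone_transforms(self, name, seed):
        # ordinal patterns depend only on ranks, not values
        x = np.random.default_rng(seed).normal(size=60)
        f = {"exp": np.exp, "cube": lambda v: v**3 + v, "affine": lambda v: 2.5 * v - 7.0}[name]
        a = ordinal_distribution(x, OrdinalConfig(D=4))
        b = ordinal_distribution(f(x), OrdinalConfig(D=4))
        assert np.array_equal(a.counts, b.counts)

    def test_white_noise_uniform_over_patterns(self):
        from scipy.stats import chisquare

        x = np.random.default_rng(7).random(2**14)
        d = ordinal_distribution(x, OrdinalConfig(D=6))
        stat, p = chisquare(d.counts)
        assert p > 1e-3  # consistent with all 720 patterns equiprobable


class TestEntropyAndComplexity:
    def test_single_pattern_entropy_zero(self):
        d = ordinal_distribution(np.arange(50.0), OrdinalConfig(D=6))
        c = statistical_complexity(d)
        assert permutation_entropy(d) == 0.0
        assert c.complexity == 0.0  # S = 0 extreme

    def test_exact_uniform_entropy_one_complexity_zero(self):
        d = OrdinalDistribution(OrdinalConfig(D=4), np.full(24, 5))
        c = statistical_complexity(d)
        assert permutation_entropy(d) == pytest.approx(1.0, abs=1e-12)
        assert jensen_shannon(d) == pytest.approx(0.0, abs=1e-12)
        assert c.complexity == pytest.approx(0.0, abs=1e-12)

    def test_white_noise_entropy_near_one(self):
        x = np.random.default_rng(3).random(2**14)
        s = permutation_entropy(ordinal_distribution(x, OrdinalConfig(D=6)))
        assert s >= 0.99

    def test_point_mass_divergence_is_one(self):
        # validates the q0 normalisation constant by construction
        for D in (2, 3, 6):
            counts = np.zeros(math.factorial(D), dtype=int)
            counts[0] = 1000
            d = OrdinalDistribution(OrdinalConfig(D=D), counts)
            assert jensen_shannon(d) == pytest.approx(1.0, abs=1e-12)

    def test_q0_closed_form_small_case(self):
        # D=2 has D!=2: bracket evaluates in closed form
        expected = -2.0 / (1.5 * math.log(3) - 2 * math.log(4) + math.log(2))
        assert q0(2) == pytest.approx(expected, rel=1e-15)

    @pytest.mark.parametrize("D", range(2, 9))
    def test_q0_positive(self, D):
        assert q0(D) > 0

    def test_q0_maximises_divergence_at_point_mass(self):
        # numerical oracle: JS against uniform over random distributions
        # never exceeds the point-mass value 1
        rng = np.random.default_rng(5)
        for _ in range(50):
            counts = rng.integers(0, 50, size=24)
            if counts.sum() == 0:
                continue
            d = OrdinalDistribution(OrdinalConfig(D=4), counts)
            assert 0.0 <= jensen_shannon(d) <= 1.0 + 1e-12

    def test_logistic_map_complexity_positive(self):
        from ordinoise.dynsys import iterate_map

        d = ordinal_distribution(iterate_map("logistic", 4.0, 2**14), OrdinalConfig(D=6))
        c = statistical_complexity(d)
        assert isinstance(c, ComplexityResult)
        assert c.complexity > 0.1
        assert c.entropy < 1.0
        assert c.complexity == pytest.approx(c.entropy * c.divergence, rel=1e-14)


class TestConfigValidation:
    @pytest.mark.parametrize("kwargs", [{"D": 1}, {"D": 2, "lag": 0}, {"tie_rule": "average"}])
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            OrdinalConfig(**kwargs)

    def test_n_patterns(self):
        assert OrdinalConfig(D=6).n_patterns == 720
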