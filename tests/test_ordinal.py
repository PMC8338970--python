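"""Ordinal encoding against a naive argsort oracle, plus entropy algebra."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from chaostoch.ordinal import (
    OrdinalConfig,
    OrdinalDistribution,
    encode_pattern,
    normalized_pe,
    pattern_codes,
    pattern_distribution,
    permutation_entropy,
)

from conftest import oracle_distribution, oracle_pattern_index


def test_worked_examples():
    # {0,5,10,13} -> "0123" (identity), {0,13,5,10} -> "0312"
    assert encode_pattern([0, 5, 10, 13]) == 0
    assert encode_pattern([0, 13, 5, 10]) == oracle_pattern_index([0, 13, 5, 10])
    assert encode_pattern([0, 13, 5, 10]) == 4  # Lehmer code of rank-string 0312


@pytest.mark.parametrize("D", [2, 4, 6, 8])
def test_descending_window_is_last_pattern(D):
    assert encode_pattern(np.arange(D)[::-1]) == math.factorial(D) - 1


def test_encoder_matches_oracle_on_random_instances():
    """Optimized Lehmer encoder == per-window argsort oracle, exactly."""
    rng = np.random.default_rng(0)
    for _ in range(1000):
        D = int(rng.integers(3, 7))
        n = int(rng.integers(D, 200))
        x = rng.normal(size=n)
        if rng.random() < 0.3:  # exercise the tie rule as well
            x = np.round(x, 1)
        codes = pattern_codes(x, OrdinalConfig(D=D))
        expected = [oracle_pattern_index(x[i : i + D]) for i in range(n - D + 1)]
        np.testing.assert_array_equal(codes, expected)


def test_tie_rule_earlier_index_ranks_lower():
    # (1, 1, 0): the earlier 1 ranks below the later 1 -> rank-string 120
    assert encode_pattern([1.0, 1.0, 0.0]) == oracle_pattern_index([1.0, 1.0, 0.0])
    # the tied pair behaves as if the later sample were slightly larger
    assert encode_pattern([1.0, 1.0, 0.0]) == encode_pattern([1.0, 1.1, 0.0])
    assert encode_pattern([1.0, 1.0, 0.0]) != encode_pattern([1.1, 1.0, 0.0])


def test_distribution_worked_example():
    x = np.array([4, 7, 9, 10, 6, 11, 3], dtype=float)
    dist = pattern_distribution(x, OrdinalConfig(D=3))
    assert dist.n_windows == 5
    np.testing.assert_allclose(dist.probs, oracle_distribution(x, 3))


def test_default_distribution_has_720_patterns():
    dist = pattern_distribution(np.random.default_rng(1).normal(size=4096))
    assert dist.probs.size == 720
    assert dist.n_windows == 4096 - 5


def test_monotone_series_single_pattern():
    dist = pattern_distribution(np.arange(100, dtype=float), OrdinalConfig(D=4))
    assert dist.probs[0] == 1.0
    assert permutation_entropy(dist) == 0.0
    assert normalized_pe(dist) == 0.0


def test_too_short_series_rejected():
    cfg = OrdinalConfig(D=6, lag=2)
    with pytest.raises(ValueError, match="shorter than the minimum"):
        pattern_codes(np.arange(10, dtype=float), cfg)


def test_lag_spacing_window_count():
    cfg = OrdinalConfig(D=3, lag=4)
    dist = pattern_distribution(np.random.default_rng(2).normal(size=50), cfg)
    assert dist.n_windows == 50 - 2 * 4


def test_entropy_of_handmade_distributions():
    cfg = OrdinalConfig(D=3)
    uniform = OrdinalDistribution(np.full(6, 1 / 6), 600, cfg)
    assert permutation_entropy(uniform) == pytest.approx(math.log(6))
    assert normalized_pe(uniform) == pytest.approx(1.0)
    two = OrdinalDistribution(np.array([0.5, 0.5, 0, 0, 0, 0.0]), 2, cfg)
    assert permutation_entropy(two) == pytest.approx(math.log(2))


def test_white_noise_entropy_near_one():
    x = np.random.default_rng(3).normal(size=2**20)
    assert normalized_pe(pattern_distribution(x)) >= 0.999


def test_distribution_validation():
    cfg = OrdinalConfig(D=3)
    with pytest.raises(ValueError):
        OrdinalDistribution(np.full(5, 0.2), 5, cfg)  # wrong length
    with pytest.raises(ValueError):
        OrdinalDistribution(np.array([0.9, 0.2, 0, 0, 0, -0.1]), 5, cfg)


def test_nonfinite_values_rejected():
    with pytest.raises(ValueError):
        encode_pattern([1.0, np.inf, 0.0])
    with pytest.raises(ValueError):
        pattern_codes(np.array([1.0, 2.0, np.nan, 4.0]), OrdinalConfig(D=3))


@settings(derandomize=True, max_examples=50, deadline=None)
@given(
    st.lists(st.integers(-10**6, 10**6), min_size=30, max_size=120, unique=True),
    st.sampled_from(["exp", "cube", "affine"]),
)
def test_distribution_invariant_under_increasing_transforms(values, transform):
    """Ordinal statistics depend only on rank order: any strictly
    increasing amplitude transform leaves the distribution bit-identical.

    Sample gaps are kept well above float precision so the transforms
    remain strictly increasing after rounding.
    """
    x = np.asarray(values, dtype=float) / 1e6
    if transform == "exp":
        y = np.exp(x)
    elif transform == "cube":
        y = x**3
    else:
        y = 2.5 * x + 7.0
    cfg = OrdinalConfig(D=4)
    np.testing.assert_array_equal(pattern_codes(x, cfg), pattern_codes(y, cfg))


@settings(derandomize=True, max_examples=50, deadline=None)
@given(st.integers(0, 2**31 - 1), st.integers(2, 6))
def test_entropy_bounds_and_window_conservation(seed, D):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=int(rng.integers(D + 1, 400)))
    cfg = OrdinalConfig(D=D)
    dist = pattern_distribution(x, cfg)
    assert dist.n_windows == x.size - (D - 1)
    assert abs(dist.probs.sum() - 1.0) < 1e-12
    sbar = normalized_pe(dist)
    assert 0.0 <= sbar <= 1.0
    if sbar == 1.0:  # S-bar = 1 iff the observed distribution is uniform
        nz = dist.probs[dist.probs > 0]
        assert np.allclose(nz, nz[0])
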