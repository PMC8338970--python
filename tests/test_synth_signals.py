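"""Generator contracts: determinism, spectra, map algebra, Lorenz maxima,
and the mixing/summing/shuffling transforms."""

import numpy as np
import pytest
from scipy import signal, stats

from chaostoch.ordinal import normalized_pe, pattern_distribution
from chaostoch.synth_signals import (
    DegenerateOrbitError,
    LorenzShortfallError,
    LorenzSpec,
    MapSpec,
    NoiseSpec,
    TimeSeries,
    generate_flicker,
    generate_fractional,
    generate_iid,
    iterate_map,
    lorenz_maxima,
    mix_signals,
    shuffle_series,
    standardize,
    sum_of_maps,
)


def _lag1(x):
    return float(np.corrcoef(x[:-1], x[1:])[0, 1])


@pytest.mark.parametrize(
    "make",
    [
        lambda s: generate_flicker(1.3, 4096, s).values,
        lambda s: generate_fractional(NoiseSpec("fbm", hurst=0.7), 4096, s).values,
        lambda s: generate_fractional(NoiseSpec("fgn", hurst=0.3), 4096, s).values,
        lambda s: generate_iid("cauchy", 4096, s).values,
        lambda s: iterate_map(MapSpec("betax"), 4096, s).values,
        lambda s: iterate_map(MapSpec("logistic"), 4096, s).values,
        lambda s: lorenz_maxima(LorenzSpec(n_maxima=64, transient_time=20.0), s).values,
        lambda s: sum_of_maps(MapSpec("logistic"), 3, 4096, s).values,
    ],
    ids=["flicker", "fbm", "fgn", "cauchy", "betax", "logistic", "lorenz", "summap"],
)
def test_generators_are_deterministic(make):
    np.testing.assert_array_equal(make(123), make(123))
    assert not np.array_equal(make(123), make(124))


@pytest.mark.parametrize("alpha", [-1.0, 0.0, 1.0, 2.0, 3.0])
def test_flicker_periodogram_slope_matches_alpha(alpha):
    """The ensemble-mean log-periodogram slope approaches -alpha."""
    n = 2**16
    p_sum = 0.0
    for s in range(50):
        x = generate_flicker(alpha, n, 9000 + s).values
        f, p = signal.periodogram(x)
        p_sum = p_sum + p
    slope = np.polyfit(np.log(f[1:]), np.log(p_sum[1:] / 50), 1)[0]
    assert slope == pytest.approx(-alpha, abs=0.15)


def test_flicker_white_noise_limit():
    x = generate_flicker(0.0, 2**16, 5).values
    assert abs(_lag1(x)) < 0.02
    assert abs(x.mean()) < 1e-12
    assert normalized_pe(pattern_distribution(x)) > 0.995


def test_flicker_rejects_silly_alpha():
    with pytest.raises(ValueError):
        generate_flicker(4.5, 1024, 0)
    with pytest.raises(ValueError):
        generate_flicker(-2.5, 1024, 0)


def test_fractional_white_noise_limits():
    fgn = generate_fractional(NoiseSpec("fgn", hurst=0.5), 2**16, 7).values
    assert abs(_lag1(fgn)) < 0.02
    fbm = generate_fractional(NoiseSpec("fbm", hurst=0.5), 2**16, 7).values
    assert abs(_lag1(np.diff(fbm))) < 0.02


def test_fgn_lag1_autocovariance_closed_form():
    """rho(1) = (2^{2H} - 2)/2 for fGn; estimated without mean subtraction
    (the sample ACF of a long-memory process is biased low)."""
    H = 0.9
    num = den = 0.0
    for s in range(50):
        x = generate_fractional(NoiseSpec("fgn", hurst=H), 2**14, 100 + s).values
        num += np.dot(x[:-1], x[1:])
        den += np.dot(x, x)
    expected = (2.0**(2 * H) - 2.0) / 2.0
    assert num / den == pytest.approx(expected, abs=0.02)
    assert num / den > 0


def test_hurst_out_of_range_rejected():
    with pytest.raises(ValueError):
        NoiseSpec("fgn", hurst=1.0)
    with pytest.raises(ValueError):
        NoiseSpec("fbm", hurst=-0.1)


@pytest.mark.parametrize("dist", ["uniform", "cauchy"])
def test_iid_noise_has_maximal_permutation_entropy(dist):
    """Ordinal statistics are rank-based, so heavy Cauchy tails change nothing."""
    x = generate_iid(dist, 2**16, 3)
    assert normalized_pe(pattern_distribution(x.values)) >= 0.995


def test_iid_degenerate_length_rejected():
    with pytest.raises(ValueError):
        generate_iid("uniform", 1, 0)


# -- maps ------------------------------------------------------------------


def test_betax_doubling_orbit():
    ts = iterate_map(MapSpec("betax", x0=0.3, transient=0), 4)
    np.testing.assert_allclose(ts.values, [0.6, 0.2, 0.4, 0.8], atol=1e-12)


def test_skewtent_first_iterate():
    ts = iterate_map(MapSpec("skewtent", x0=0.1, transient=0), 2)
    assert ts.values[0] == pytest.approx(0.1 / 0.1847, abs=1e-12)


def test_logistic_fixed_point_is_degenerate():
    with pytest.raises(DegenerateOrbitError):
        iterate_map(MapSpec("logistic", x0=0.5, transient=0), 10)


@pytest.mark.parametrize("map_id", ["betax", "logistic", "schuster", "skewtent"])
def test_map_iterates_stay_in_unit_interval(map_id):
    x = iterate_map(MapSpec(map_id), 2**14, 21).values
    assert np.all(x >= 0.0) and np.all(x <= 1.0)


def test_schuster_exponent_is_configurable():
    # both printed parameterizations must be runnable
    for z in (0.5, 1.5):
        x = iterate_map(MapSpec("schuster", parameter=z), 2048, 5).values
        assert np.all((x >= 0) & (x <= 1))


# -- Lorenz ----------------------------------------------------------------


def test_lorenz_chaotic_maxima_are_nonperiodic():
    ts = lorenz_maxima(LorenzSpec(n_maxima=1000), 1)
    assert len(np.unique(np.round(ts.values, 6))) > 100


def test_lorenz_subthreshold_reports_shortfall():
    with pytest.raises(LorenzShortfallError):
        lorenz_maxima(LorenzSpec(R=10.0, n_maxima=1000), 1)


def test_lorenz_dt_self_convergence():
    """Halving dt moves the early maxima by <1e-3 (before chaotic
    divergence of the two discretizations takes over)."""
    a = lorenz_maxima(LorenzSpec(transient_time=1.0, n_maxima=5), 7).values
    b = lorenz_maxima(LorenzSpec(dt=0.0025, transient_time=1.0, n_maxima=5), 7).values
    assert np.max(np.abs(a - b)) < 1e-3


# -- transforms ------------------------------------------------------------


def test_mix_endpoints_and_arithmetic():
    x = generate_iid("gaussian", 256, 1)
    y = generate_iid("gaussian", 256, 2)
    np.testing.assert_allclose(mix_signals(x, y, 0.0).values, standardize(x.values))
    np.testing.assert_allclose(mix_signals(x, y, 1.0).values, standardize(y.values))
    z = mix_signals(TimeSeries([1.0, -1.0]), TimeSeries([3.0, 1.0]), 0.5, standardize_inputs=False)
    np.testing.assert_allclose(z.values, [2.0, 0.0])


def test_mix_linearity():
    x = generate_iid("uniform", 512, 3)
    y = generate_iid("uniform", 512, 4)
    lhs = mix_signals(x, y, 0.3).values + mix_signals(y, x, 0.3).values
    np.testing.assert_allclose(lhs, standardize(x.values) + standardize(y.values), atol=1e-12)


def test_mix_rejects_bad_eta_and_lengths():
    x = generate_iid("uniform", 128, 1)
    with pytest.raises(ValueError):
        mix_signals(x, x, 1.5)
    with pytest.raises(ValueError):
        mix_signals(x, generate_iid("uniform", 64, 2), 0.5)


def test_sum_of_maps_single_replicate_matches_iterate():
    seed = 99
    child = np.random.SeedSequence(seed).spawn(1)[0]
    direct = standardize(iterate_map(MapSpec("logistic"), 2048, child).values)
    summed = sum_of_maps(MapSpec("logistic"), 1, 2048, seed).values
    np.testing.assert_allclose(summed, direct, atol=1e-12)


def test_sum_of_many_maps_approaches_gaussian():
    x = sum_of_maps(MapSpec("logistic"), 100, 2**17, 5).values
    assert stats.kurtosis(x) == pytest.approx(0.0, abs=0.2)


def test_shuffle_preserves_multiset():
    x = iterate_map(MapSpec("logistic"), 4096, 8)
    y = shuffle_series(x, 9)
    np.testing.assert_array_equal(np.sort(y.values), np.sort(x.values))
    assert not np.array_equal(y.values, x.values)


def test_shuffle_length_one_unchanged():
    out = shuffle_series(np.array([3.14]), 0)
    np.testing.assert_array_equal(out, [3.14])


def test_shuffled_chaos_has_maximal_entropy():
    x = iterate_map(MapSpec("logistic"), 2**16, 10)
    assert normalized_pe(pattern_distribution(shuffle_series(x, 11).values)) >= 0.995


def test_timeseries_invariants():
    with pytest.raises(ValueError):
        TimeSeries([1.0])
    with pytest.raises(ValueError):
        TimeSeries([1.0, np.nan])
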