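import numpy as np
import pytest
from scipy.special import gamma

import rtdcca as rt
from rtdcca.simulate import McArfimaParams, SpikeSpec


# -- ARFIMA weights -------------------------------------------------------

def test_arfima_weights_vanish_at_d_zero():
    assert np.array_equal(rt.arfima_weights(0.0, 10), np.zeros(10))


@pytest.mark.parametrize("d", [0.1, 0.3, 0.45])
def test_first_weight_equals_d(d):
    assert rt.arfima_weights(d, 5)[0] == pytest.approx(d, rel=1e-12)


def test_arfima_weights_match_direct_gamma_ratio():
    d = 0.3
    n = np.arange(1, 51, dtype=float)
    direct = d * gamma(n - d) / (gamma(1 - d) * gamma(n + 1))
    np.testing.assert_allclose(rt.arfima_weights(d, 50), direct, rtol=1e-10)


def test_arfima_weights_reject_invalid_inputs():
    with pytest.raises(ValueError):
        rt.arfima_weights(0.5, 10)
    with pytest.raises(ValueError):
        rt.arfima_weights(-0.1, 10)
    with pytest.raises(ValueError):
        rt.arfima_weights(0.3, 0)


# -- single ARFIMA --------------------------------------------------------

def test_simulate_arfima_deterministic_and_sized():
    a = rt.simulate_arfima(0.3, 256, seed=42)
    b = rt.simulate_arfima(0.3, 256, seed=42)
    assert a.shape == (256,)
    assert np.array_equal(a, b)
    assert not np.array_equal(a, rt.simulate_arfima(0.3, 256, seed=43))


def test_simulate_arfima_d_zero_is_iid_gaussian():
    x = rt.simulate_arfima(0.0, 4096, seed=5)
    # lag-1 autocorrelation of white noise is O(1/sqrt(N))
    r1 = np.corrcoef(x[:-1], x[1:])[0, 1]
    assert abs(r1) < 0.08
    assert np.var(x) == pytest.approx(1.0, rel=0.15)


def test_simulate_arfima_rejects_short_series():
    with pytest.raises(ValueError):
        rt.simulate_arfima(0.3, 32, seed=0)


@pytest.mark.parametrize("d", [0.0, 0.2, 0.4])
def test_dfa_exponent_recovers_half_plus_d(d):
    """alpha = 0.5 + d for fractionally integrated noise (50 replicates)."""
    N = 2**13
    scales = rt.preset_for_length(N)
    alphas = []
    for child in np.random.SeedSequence(2024).spawn(50):
        x = rt.simulate_arfima(d, N, np.random.default_rng(child))
        alphas.append(rt.fit_exponent(scales, np.sqrt(rt.dfa_blocked(x, scales))))
    assert np.mean(alphas) == pytest.approx(0.5 + d, abs=0.05)


# -- mc-ARFIMA pairs ------------------------------------------------------

def test_default_params_match_cross_persistent_setting():
    p = rt.DEFAULT_MC_ARFIMA
    assert p.weights == (0.2, 1.0, 1.0, 0.2)
    assert p.d == (0.4, 0.3, 0.3, 0.4)
    cov = p.covariance()
    assert cov[1, 2] == 0.9
    np.testing.assert_array_equal(np.diag(cov), 1.0)
    assert cov[0, 3] == 0.0


def test_mc_arfima_seed_reproducibility():
    x1, y1 = rt.simulate_mc_arfima(rt.DEFAULT_MC_ARFIMA, 128, seed=9)
    x2, y2 = rt.simulate_mc_arfima(rt.DEFAULT_MC_ARFIMA, 128, seed=9)
    assert np.array_equal(x1, x2) and np.array_equal(y1, y2)


def test_uncorrelated_innovations_give_uncorrelated_pair():
    params = McArfimaParams(rho=np.eye(4))
    rs = []
    for child in np.random.SeedSequence(77).spawn(20):
        x, y = rt.simulate_mc_arfima(params, 2048, np.random.default_rng(child))
        rs.append(np.corrcoef(x, y)[0, 1])
    assert abs(np.mean(rs)) < 0.05


def test_mc_arfima_parameter_symmetry_swaps_roles():
    """Swapping (w1,d1,w2,d2) with (w4,d4,w3,d3) plus relabeling the
    innovations mirrors the construction, so the innovation covariance and
    the marginal statistics of x and y trade places."""
    p = rt.DEFAULT_MC_ARFIMA
    perm = [3, 2, 1, 0]
    swapped = McArfimaParams(
        weights=tuple(p.weights[i] for i in perm),
        d=tuple(p.d[i] for i in perm),
        sigma2=tuple(p.sigma2[i] for i in perm),
        rho=p.rho[np.ix_(perm, perm)],
    )
    np.testing.assert_array_equal(
        swapped.covariance(), p.covariance()[np.ix_(perm, perm)]
    )
    vx, vy, wx, wy = [], [], [], []
    for child in np.random.SeedSequence(31).spawn(30):
        rng = np.random.default_rng(child)
        x, y = rt.simulate_mc_arfima(p, 1024, rng)
        xs, ys = rt.simulate_mc_arfima(swapped, 1024, np.random.default_rng(child))
        vx.append(np.var(x)), vy.append(np.var(y))
        wx.append(np.var(xs)), wy.append(np.var(ys))
    assert np.mean(wx) == pytest.approx(np.mean(vy), rel=0.15)
    assert np.mean(wy) == pytest.approx(np.mean(vx), rel=0.15)


def test_mc_arfima_rejects_invalid_covariance():
    bad = np.eye(4)
    bad[1, 2] = bad[2, 1] = 1.5  # not PSD with unit variances
    with pytest.raises(ValueError, match="semi-definite"):
        McArfimaParams(rho=bad)


def test_memory_parameters_validated():
    with pytest.raises(ValueError):
        McArfimaParams(d=(0.4, 0.55, 0.3, 0.4))
    with pytest.raises(ValueError):
        McArfimaParams(d=(0.4, 0.0, 0.3, 0.4))
    p = McArfimaParams(d=(0.4, 0.0, 0.3, 0.4), allow_d_zero=True)
    assert p.d[1] == 0.0


# -- white-noise contamination -------------------------------------------

def test_white_noise_variance_additivity():
    x = rt.simulate_arfima(0.3, 2048, seed=3)
    snr = 4.0
    ratios = []
    for child in np.random.SeedSequence(8).spawn(100):
        xc = rt.add_white_noise(x, snr, np.random.default_rng(child))
        ratios.append(np.var(xc) / np.var(x))
    assert np.mean(ratios) == pytest.approx(1.0 + 1.0 / snr, rel=0.02)


def test_white_noise_snr_one_doubles_variance():
    x = rt.simulate_arfima(0.3, 4096, seed=4)
    noise = rt.add_white_noise(x, 1.0, seed=0) - x
    assert np.var(noise) == pytest.approx(np.var(x), rel=0.1)


def test_white_noise_high_snr_limit_and_errors():
    x = rt.simulate_arfima(0.3, 256, seed=5)
    xc = rt.add_white_noise(x, 1e12, seed=0)
    assert np.max(np.abs(xc - x)) < 1e-4
    with pytest.raises(ValueError, match="positive"):
        rt.add_white_noise(x, 0.0, seed=0)
    with pytest.raises(ValueError, match="constant"):
        rt.add_white_noise(np.ones(64), 10.0, seed=0)


# -- spike contamination --------------------------------------------------

def test_type_a_leaves_second_series_untouched(rng):
    x, y = rng.standard_normal((2, 1024))
    xc, yc = rt.add_spikes(x, y, SpikeSpec(kind="A"), seed=1)
    assert np.array_equal(yc, y)
    assert not np.array_equal(xc, x)


def test_type_c_shares_artifact_between_equal_variance_hosts(rng):
    x = rng.standard_normal(1024)
    y = -x  # equal variance host
    xc, yc = rt.add_spikes(x, y, SpikeSpec(kind="C"), seed=2)
    np.testing.assert_allclose(xc - x, yc - y, atol=1e-12)


def test_type_b_places_independent_artifacts(rng):
    x, y = rng.standard_normal((2, 1024))
    xc, yc = rt.add_spikes(x, y, SpikeSpec(kind="B"), seed=3)
    assert not np.array_equal(np.flatnonzero(xc != x), np.flatnonzero(yc != y))


def test_spike_peak_is_amplitude_times_variance(rng):
    x, y = rng.standard_normal((2, 2048))
    spec = SpikeSpec()
    xc, _ = rt.add_spikes(x, y, spec, seed=4)
    delta = xc - x
    assert delta.max() == pytest.approx(4.0 * np.var(x), rel=1e-12)
    # sd-scaled variant
    xc2, _ = rt.add_spikes(x, y, SpikeSpec(amplitude_units="sd"), seed=4)
    assert (xc2 - x).max() == pytest.approx(4.0 * np.std(x), rel=1e-12)


def test_spikes_nonoverlapping_and_fully_inside(rng):
    x, y = rng.standard_normal((2, 1024))
    spec = SpikeSpec(count=10, width=20)
    xc, _ = rt.add_spikes(x, y, spec, seed=5)
    support = np.flatnonzero(xc != x)
    # hanning endpoints are zero: each bump touches width-2 samples
    assert support.size == spec.count * (spec.width - 2)
    starts = support[np.diff(support, prepend=-10) > 1]
    assert starts.size == spec.count
    assert np.all(np.diff(np.sort(starts)) >= spec.width)


def test_spikes_rejected_when_they_cannot_fit(rng):
    x, y = rng.standard_normal((2, 128))
    with pytest.raises((ValueError, RuntimeError)):
        rt.add_spikes(x, y, SpikeSpec(count=10, width=20), seed=6)


def test_spike_spec_validation():
    with pytest.raises(ValueError):
        SpikeSpec(kind="D")
    with pytest.raises(ValueError):
        SpikeSpec(amplitude_units="mad")
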