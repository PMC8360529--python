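import numpy as np
import pytest

import mgam
from mgam.ar import ArParams, simulate_ar
from mgam.diagnostics import (acf, durbin_levinson_pacf,
                              noise_corrected_pacf, pacf, whiteness_check)


def _ar1_acf_se(rho, k, n):
    """Bartlett standard error of the sample ACF of an AR(1) at lag k."""
    var = ((1 + rho ** 2) * (1 - rho ** (2 * k)) / (1 - rho ** 2)
           - 2 * k * rho ** (2 * k)) / n
    return np.sqrt(var)


def test_acf_of_ar1_matches_closed_form():
    n = 5000
    rho = 0.6
    x = simulate_ar(ArParams(1, np.array([rho]), 1.0), n,
                    np.random.default_rng(42))
    r = acf(x, 5)
    for k in range(1, 6):
        assert abs(r[k - 1] - rho ** k) < 3 * _ar1_acf_se(rho, k, n)


def test_acf_of_white_noise_is_small():
    hits = 0
    for seed in range(10):
        x = np.random.default_rng(seed).normal(size=5000)
        hits += np.all(np.abs(acf(x, 10)) < 0.05)
    assert hits >= 9


def test_acf_rejects_constant_series():
    with pytest.raises(ValueError, match="constant"):
        acf(np.ones(100), 5)


def test_pacf_base_case_equals_acf():
    x = np.random.default_rng(7).normal(size=500).cumsum()
    assert pacf(x, 5)[0] == pytest.approx(acf(x, 5)[0], abs=1e-12)


def test_pacf_matches_statsmodels_yule_walker_exactly():
    from statsmodels.tsa.stattools import pacf_yw

    x = simulate_ar(ArParams(2, np.array([0.5, 0.2]), 1.0), 1000,
                    np.random.default_rng(8))
    ours = pacf(x, 10)
    ref = pacf_yw(x, nlags=10, method="mle")[1:]
    assert np.allclose(ours, ref, atol=1e-10)


def test_pacf_close_to_ols_ar_regression():
    """DL-on-ACF (Yule–Walker) and OLS AR(k) agree up to O(1/n) edge
    effects."""
    n = 2000
    x = simulate_ar(ArParams(2, np.array([0.5, 0.2]), 1.0), n,
                    np.random.default_rng(9))
    ours = pacf(x, 4)
    for k in range(1, 5):
        xc = x - x.mean()
        Y = xc[k:]
        X = np.column_stack([xc[k - j: n - j] for j in range(1, k + 1)])
        beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
        assert abs(ours[k - 1] - beta[-1]) < 5e-3


def test_pacf_cuts_off_beyond_ar_order():
    x = simulate_ar(ArParams(2, np.array([0.5, 0.2]), 1.0), 5000,
                    np.random.default_rng(10))
    p = pacf(x, 8)
    assert abs(p[0]) > 0.3 and abs(p[1]) > 0.1
    assert np.all(np.abs(p[2:]) < 0.06)


def test_white_noise_pacf_near_zero():
    x = np.random.default_rng(11).normal(size=5000)
    assert np.all(np.abs(pacf(x, 10)) < 0.05)


def test_whiteness_check_trivial_pass_and_fields():
    x = np.random.default_rng(12).normal(size=2000)
    rep = whiteness_check(x)
    assert rep.passes
    assert rep.threshold == 0.10
    assert len(rep.acf) == len(rep.pacf) == 30
    assert rep.large_sample_band == pytest.approx(1.96 / np.sqrt(2000))
    frame = rep.to_frame()
    assert frame["pass"].all()


def test_whiteness_monotone_in_threshold():
    x = simulate_ar(ArParams(1, np.array([0.3]), 1.0), 800,
                    np.random.default_rng(13))
    strict = whiteness_check(x, threshold=0.10)
    loose = whiteness_check(x, threshold=0.3)
    assert np.all(loose.pass_per_lag >= strict.pass_per_lag)


def test_durbin_levinson_recovers_ar_coefficients_from_true_acf():
    phi = np.array([0.5, 0.2])
    from mgam.ar import autocovariances

    gam = autocovariances(phi, 1.0, 6)
    p = durbin_levinson_pacf(gam / gam[0])
    assert p[1] == pytest.approx(phi[1], abs=1e-10)  # pacf(p) = phi_p
    assert np.allclose(p[2:], 0.0, atol=1e-10)


def test_noise_corrected_pacf_sees_through_measurement_noise():
    rng = np.random.default_rng(14)
    b = simulate_ar(ArParams(2, np.array([0.5, 0.2]), 0.013), 5000, rng)
    noise_var = 0.011
    y = b + rng.normal(0, np.sqrt(noise_var), 5000)
    corrected = noise_corrected_pacf(y, noise_var, 4)
    # sampling sd of the corrected pacf is inflated by the noise ratio
    # (gamma_obs(0)/gamma_b(0) ~ 1.5), so ~0.03 at n=5000; allow 3 sd
    assert corrected[1] == pytest.approx(0.2, abs=0.09)
    # raw pacf is attenuated by the noise
    assert pacf(y, 2)[1] < corrected[1]


def test_noise_corrected_pacf_of_pure_noise_is_zero():
    rng = np.random.default_rng(15)
    y = rng.normal(0, 0.1, 3000)
    assert np.allclose(noise_corrected_pacf(y, 0.01, 5), 0.0)


def test_select_ar_order_recovers_two_on_latent_ar2_data():
    hits = 0
    for seed in range(20):
        exposure, counts, truth = mgam.simulate(seed=300 + seed)
        rep = mgam.select_ar_order(
            exposure, counts, p_max=4,
            weights=truth.config.true_weights())
        hits += rep.selected == 2
    assert hits >= 16


def test_select_ar_order_zero_on_independent_data():
    cfg = mgam.SynthConfig(sigma2=0.0)
    exposure, counts, truth = mgam.simulate(cfg, seed=16)
    rep = mgam.select_ar_order(exposure, counts, p_max=3,
                               weights=truth.config.true_weights())
    assert rep.selected == 0
    assert rep.all_pass
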