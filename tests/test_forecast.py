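import numpy as np
import pandas as pd
import pytest

import mgam
from mgam.ar import ArParams
from mgam.forecast import propagate_latent


def test_latent_recursion_matches_hand_ar1():
    phi = np.array([0.7])
    out = propagate_latent(phi, np.array([2.0]), 5)
    assert np.allclose(out, 2.0 * 0.7 ** np.arange(1, 6))


def test_latent_recursion_matches_hand_ar2():
    phi = np.array([0.5, 0.2])
    hist = [0.3, 1.0]  # b_{T-1}, b_T
    expected = []
    for _ in range(4):
        nxt = 0.5 * hist[-1] + 0.2 * hist[-2]
        expected.append(nxt)
        hist.append(nxt)
    assert np.allclose(propagate_latent(phi, np.array([0.3, 1.0]), 4),
                       expected)


def test_zero_phi_forecast_equals_fixed_effect_prediction(
        train_test_split):
    train_exp, train, full_exp, test, truth = train_test_split
    m = mgam.MGAM(train_exp, train, ar_order=1).fit(
        fix_ar=ArParams(1, np.array([0.0]), 0.01))
    dates = test.index[:90]
    fc = m.predict(full_exp, dates)
    assert np.allclose(fc.latent, 0.0)
    assert np.allclose(fc.mu, np.exp(fc.fixed_eta))


def test_forecast_decays_to_fixed_effect_mean(train_test_split):
    train_exp, train, full_exp, test, truth = train_test_split
    m = mgam.fit_mgam(train_exp, train, ar_order=2,
                      weights=truth.config.true_weights())
    fc = m.predict(full_exp, test.index)
    # geometric decay of the latent path to zero
    assert abs(fc.latent[-1]) < 1e-6
    assert abs(fc.latent[-1]) <= abs(fc.latent[0])
    assert np.allclose(fc.mu[-30:], np.exp(fc.fixed_eta[-30:]))


def test_no_lookahead_in_predictions(default_sim):
    """Altering counts after the forecast origin cannot change the
    forecast."""
    exposure, counts, truth = default_sim
    series = counts.stratum()
    train = series.loc[:"2010-12-31"]
    train_exp = mgam.ExposureSeries(exposure.data.loc[:"2010-12-31"])
    tampered = series.copy()
    tampered.loc["2011-06-01":] = 1
    m1 = mgam.fit_mgam(train_exp, train, ar_order=2,
                       weights=truth.config.true_weights())
    m2 = mgam.fit_mgam(train_exp, tampered.loc[:"2010-12-31"], ar_order=2,
                       weights=truth.config.true_weights())
    dates = series.loc["2011-01-01":].index
    assert np.array_equal(m1.predict(exposure, dates).mu,
                          m2.predict(exposure, dates).mu)


def test_forecast_rejects_in_sample_dates_and_gaps(train_test_split):
    train_exp, train, full_exp, test, truth = train_test_split
    m = mgam.fit_mgam(train_exp, train, ar_order=2,
                      weights=truth.config.true_weights())
    with pytest.raises(ValueError, match="after the training window"):
        m.predict(full_exp, pd.DatetimeIndex(["2010-06-01"]))
    with pytest.raises(ValueError, match="does not cover"):
        m.predict(full_exp, pd.DatetimeIndex(["2013-01-01"]))


def test_validation_trivial_cases(train_test_split):
    from mgam.forecast import ForecastResult, validate

    dates = pd.date_range("2012-01-01", periods=5)
    mu = np.array([1.0, 3.0, 2.0, 5.0, 4.0])
    fc = ForecastResult(dates=dates, mu=mu, latent=np.zeros(5),
                        fixed_eta=np.log(mu))
    assert validate(fc, mu) == pytest.approx(1.0)
    assert validate(fc, mu.max() + mu.min() - mu) == pytest.approx(-1.0)
    with pytest.raises(ValueError, match="ties"):
        validate(fc, np.ones(5))


def test_holdout_year_rank_correlation_tracks_oracle():
    """Fit on the first four years, forecast the fifth; the fitted
    forecast's Spearman correlation with the observed counts approaches
    the oracle forecast computed from the generating fixed effects (the
    ceiling set by the unpredictable latent and Poisson noise)."""
    from scipy import stats

    rhos, oracle = [], []
    for seed in range(20):
        exposure, counts, truth = mgam.simulate(seed=400 + seed)
        series = counts.stratum()
        mask = series.index >= "2011-01-01"
        mu_true_fixed = np.exp(truth.eta_fixed[np.asarray(mask)])
        oracle.append(
            stats.spearmanr(mu_true_fixed, series[mask]).statistic)
        train = series.loc[:"2010-12-31"]
        train_exp = mgam.ExposureSeries(exposure.data.loc[:"2010-12-31"])
        m = mgam.fit_mgam(train_exp, train, ar_order=2,
                          weights=truth.config.true_weights())
        fc = m.predict(exposure, series[mask].index)
        rhos.append(fc.validate(series[mask]))
    assert np.median(oracle) > 0.6  # the year is genuinely predictable
    assert np.median(rhos) >= np.median(oracle) - 0.1
    assert np.median(rhos) >= 0.5
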