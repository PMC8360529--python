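import numpy as np
import pandas as pd
import pytest

import mgam
from mgam.ar import autocovariances
from mgam.simulate import SynthConfig, simulate


def test_same_seed_bit_identical():
    e1, c1, t1 = simulate(seed=5)
    e2, c2, t2 = simulate(seed=5)
    pd.testing.assert_frame_equal(e1.data, e2.data)
    pd.testing.assert_frame_equal(c1.data, c2.data)
    assert np.array_equal(t1.latent, t2.latent)
    e3, _, _ = simulate(seed=6)
    assert not e3.data.equals(e1.data)


def test_generated_series_satisfy_container_invariants(default_sim):
    exposure, counts, truth = default_sim
    # containers re-validate on construction; rebuilding must succeed
    mgam.ExposureSeries(exposure.data)
    mgam.CountSeries(counts.data)
    y = counts.stratum()
    assert (y >= 0).all()
    assert len(y) == truth.config.n_days
    # exposure has the 6-day lag lead-in before the first count date
    assert exposure.dates[0] == y.index[0] - pd.Timedelta(days=6)


def test_degenerate_generator_is_iid_poisson():
    cfg = SynthConfig(
        sigma2=0.0, zone_slopes=(0.0, 0.0, 0.0), trend_per_year=0.0,
        confound_amplitude=0.0, beta_pm10=0.0,
        weekday_effects=(0.0,) * 6, baseline_log_rate=np.log(50.0),
    )
    _, counts, truth = simulate(cfg, seed=17)
    y = counts.stratum().to_numpy()
    assert np.allclose(truth.mu, 50.0)
    se = np.sqrt(50.0 / len(y))
    assert abs(y.mean() - 50.0) < 3 * se
    assert abs(mgam.acf(y.astype(float), 1)[0]) < 0.08


def test_latent_autocorrelation_matches_yule_walker_oracle():
    cfg = SynthConfig(n_days=5000)
    _, _, truth = simulate(cfg, seed=18)
    b = truth.latent
    gam = autocovariances(np.array(cfg.phi), cfg.sigma2, 3)
    rho_true = gam[1:] / gam[0]
    r = mgam.acf(b, 3)
    n = len(b)
    for k in range(3):
        # generous Monte-Carlo band for a correlated series
        assert abs(r[k] - rho_true[k]) < 3 * 2.0 / np.sqrt(n)


def test_temperature_and_pm10_negatively_correlated(default_sim):
    exposure, _, _ = default_sim
    rho = mgam.correlate(exposure.data["tmean"], exposure.data["pm10"])
    assert rho < -0.05


def test_invalid_configs_rejected():
    with pytest.raises(ValueError, match="lag_weights"):
        simulate(SynthConfig(lag_weights=(1.0,) * 7))
    with pytest.raises(ValueError, match="non-stationary"):
        simulate(SynthConfig(phi=(1.2, 0.3)))
    with pytest.raises(ValueError, match="outside"):
        simulate(SynthConfig(baseline_log_rate=np.log(2000.0)))


def test_score_recovery_of_truth_is_exact(default_sim, mgam_fit):
    _, _, truth = default_sim

    class Oracle:
        lag_weights = truth.config.true_weights()
        ar_params = truth.config.ar_params

        def temperature_effect(self, n_grid=200):
            from mgam.effects import EffectCurve

            return EffectCurve(
                grid=truth.effect_grid, eta=truth.effect_values,
                se=np.zeros_like(truth.effect_grid),
                reference=truth.config.temp_mean, df=5)

        def diagnostics(self):
            raise RuntimeError("no residuals for the oracle")

    table = mgam.score_recovery(truth, Oracle())
    assert table.loc["w_rmse", "estimate"] == 0.0
    assert abs(table.loc["phi1", "error"]) == 0.0
    assert table.loc["curve_correlation", "estimate"] == pytest.approx(1.0)


def test_score_recovery_flags_misspecified_model(default_sim):
    exposure, counts, truth = default_sim
    gam_as_mgam = mgam.fit_mgam(exposure, counts, ar_order=0,
                                weights=truth.config.true_weights())
    table = mgam.score_recovery(truth, gam_as_mgam)
    # p=0 on AR(2) data: whiteness fails and phi errors are large
    assert table.loc["whiteness_pass", "estimate"] == 0.0
    assert abs(table.loc["phi1", "error"]) == pytest.approx(0.5)
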