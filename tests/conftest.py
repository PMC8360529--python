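import numpy as np
import pytest

import mgam


@pytest.fixture(scope="session")
def default_sim():
    """One default synthetic dataset (Shanghai-like conditions, seed 1)."""
    return mgam.simulate(seed=1)


@pytest.fixture(scope="session")
def gam_fit(default_sim):
    exposure, counts, truth = default_sim
    return mgam.fit_gam(exposure, counts)


@pytest.fixture(scope="session")
def mgam_fit(default_sim):
    """MGAM fit at the true lag weights (fast; weight estimation is
    exercised separately)."""
    exposure, counts, truth = default_sim
    return mgam.fit_mgam(
        exposure, counts, ar_order=2, weights=truth.config.true_weights()
    )


@pytest.fixture(scope="session")
def train_test_split(default_sim):
    """First four years for training, final year held out."""
    exposure, counts, truth = default_sim
    series = counts.stratum()
    train = series.loc[:"2010-12-31"]
    test = series.loc["2011-01-01":]
    train_exposure = mgam.ExposureSeries(
        exposure.data.loc[:"2010-12-31"]
    )
    return train_exposure, train, exposure, test, truth
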