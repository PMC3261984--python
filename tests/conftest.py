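import numpy as np
import pytest

import dlnmcc as d


@pytest.fixture(scope="session")
def tianjin_series():
    series, truth = d.generate(d.scenario("tianjin_like", n_days=1095, seed=11))
    return series, truth


@pytest.fixture(scope="session")
def both_series():
    series, truth = d.generate(d.scenario("both-effects", n_days=1095, seed=5))
    return series, truth


@pytest.fixture(scope="session")
def spline_results(tianjin_series):
    series, _ = tianjin_series
    return d.TemperatureLagModel(series, outcome="nonaccidental").fit()


@pytest.fixture(scope="session")
def threshold_results(both_series):
    series, truth = both_series
    model = d.TemperatureLagModel(
        series, exposure=d.ThresholdSpec(truth.cold_threshold, truth.hot_threshold))
    return model.fit()


@pytest.fixture
def rng():
    return np.random.default_rng(20260101)
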