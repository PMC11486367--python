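import pytest

from ponv_cea import AFTParameters, calibrate, default_parameter_set, make_model

#: published Weibull time-to-PONV laws (location/scale, time in days)
RAMOSETRON_WEIBULL = AFTParameters("weibull", intercept=-2.0997, log_scale=0.8475)
NO_ANTIEMETIC_WEIBULL = AFTParameters("weibull", intercept=-2.7831, log_scale=0.7985)


@pytest.fixture(scope="session")
def base_params():
    return default_parameter_set()


@pytest.fixture(scope="session")
def calibrations(base_params):
    return calibrate(base_params)


@pytest.fixture(scope="session")
def calibrated_model(base_params):
    return make_model(base_params, calibrated=True)
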