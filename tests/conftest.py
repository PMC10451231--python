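import numpy as np
import pytest

from dosekit import (
    IntegralControllerConfig,
    RateConstants,
    build_continuous_model,
    make_interval,
    zoh_discretize,
)

NOMINAL = dict(ka=0.0370, ke1=0.1214, k23=1.2725, ke3=0.2171)

# published 4-dp reference values for the T = 6 h discretization
F_REF = np.array(
    [
        [0.3866, 0.0, 0.0],
        [0.0128, 0.0005, 0.0],
        [0.0718, 0.3272, 0.2718],
    ]
)
G_REF = np.array([3.8726, 0.1025, 0.2704])
GAIN_REF = 1.0759
OPENLOOP_DOSE_REF = 46.4727
K_REF = np.array([-0.2371, 0.0754, 0.0754])

TABLE2_U = [15.00, 28.78, 39.71, 47.14, 51.26, 52.77, 52.52, 51.31, 49.77, 48.30]
TABLE2_Y = [0.0, 4.05, 13.55, 25.24, 36.25, 44.96, 50.82, 54.03, 55.15, 54.88]


@pytest.fixture(scope="session")
def nominal_rates():
    return RateConstants(**NOMINAL)


@pytest.fixture(scope="session")
def cont_model(nominal_rates):
    return build_continuous_model(nominal_rates)


@pytest.fixture(scope="session")
def disc_model(cont_model):
    return zoh_discretize(cont_model, 6.0)


@pytest.fixture(scope="session")
def interval(disc_model):
    return make_interval(disc_model, 0.1)


@pytest.fixture()
def ki03_cfg():
    return IntegralControllerConfig(ki=0.3, r=50.0, horizon=24)
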