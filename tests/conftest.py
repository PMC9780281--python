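import numpy as np
import pytest

from psmcea import SurvivalDistribution, load_baseline

# Published distribution parameters used throughout the tests (months).
ITT_PEMBRO_OS = {"family": "lognormal", "params": {"meanlog": 1.95, "sdlog": 1.04}}
ITT_PEMBRO_PFS = {"family": "loglogistic", "params": {"shape": 1.882, "scale": 2.742}}
ITT_CHEMO_OS = {"family": "gamma", "params": {"shape": 1.4504, "rate": 0.1728}}
ITT_CHEMO_PFS = {"family": "lognormal", "params": {"meanlog": 1.27, "sdlog": 0.9}}

#: One representative, all-positive-parameter spec per family.
EXAMPLE_SPECS = {
    "exponential": SurvivalDistribution("exponential", {"rate": 0.12}),
    "weibull": SurvivalDistribution("weibull", {"shape": 1.3, "scale": 8.0}),
    "gamma": SurvivalDistribution("gamma", {"shape": 1.4504, "rate": 0.1728}),
    "lognormal": SurvivalDistribution("lognormal", {"meanlog": 1.95, "sdlog": 1.04}),
    "loglogistic": SurvivalDistribution("loglogistic", {"shape": 1.882, "scale": 2.742}),
    "gompertz": SurvivalDistribution("gompertz", {"shape": 0.05, "rate": 0.08}),
}


@pytest.fixture(scope="session")
def itt_config():
    return load_baseline("ITT")


@pytest.fixture(scope="session")
def escc_config():
    return load_baseline("ESCC")


@pytest.fixture(scope="session")
def cps10_config():
    return load_baseline("CPS10")


@pytest.fixture(scope="session")
def all_configs(itt_config, escc_config, cps10_config):
    return {"ITT": itt_config, "ESCC": escc_config, "CPS10": cps10_config}


@pytest.fixture
def rng():
    return np.random.default_rng(20220941)
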