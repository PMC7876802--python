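import warnings

import numpy as np
import pytest

from trajsurv import simgen
from trajsurv.study import generate_rizopoulos


@pytest.fixture(autouse=True)
def _quiet_warnings():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        yield


@pytest.fixture(scope="session")
def table1_params():
    """Framingham-like generation defaults with a moderate event rate."""
    return simgen.GenParams(gamma=0.5, lam=4.2e-6, nu=1.5, n=100, seed=11)


@pytest.fixture(scope="session")
def small_dataset(table1_params):
    """100 subjects, Weibull plug-in scheme, ~10% censoring."""
    return simgen.generate_dataset(table1_params)


@pytest.fixture(scope="session")
def null_dataset():
    """gamma = 0 dataset (trajectory unrelated to survival)."""
    params = simgen.GenParams(gamma=0.0, lam=3e-4, nu=1.5, n=150, seed=5)
    return simgen.generate_dataset(params), params


@pytest.fixture(scope="session")
def selfconsistent_dataset():
    """Integrated-hazard generation, matching the joint fitting model."""
    params = simgen.GenParams(gamma=0.5, lam=1e-6, nu=1.5, n=200, seed=42)
    return generate_rizopoulos(params), params
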