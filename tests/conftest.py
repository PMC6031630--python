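import logging

import pytest

import igdose as ig


@pytest.fixture(autouse=True)
def _quiet_clamp_warnings():
    """Silence per-procedure clamp warnings in bulk cohort runs."""
    logger = logging.getLogger("igdose.dose")
    old = logger.level
    logger.setLevel(logging.ERROR)
    yield
    logger.setLevel(old)


@pytest.fixture(scope="session")
def dose_params():
    return ig.default_dose_params()


@pytest.fixture(scope="session")
def risk_coeffs():
    return ig.default_risk_coefficients()


@pytest.fixture(scope="session")
def life_tables():
    return ig.default_life_tables()


@pytest.fixture(scope="session")
def fee_schedule():
    return ig.default_fee_schedule()
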