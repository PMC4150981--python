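import pytest

import markovcea as m


@pytest.fixture(scope="session")
def params():
    """The published parameterisation (session-wide, treated read-only)."""
    return m.published_parameters()


@pytest.fixture(scope="session")
def calibrated_ages(params):
    """Start ages pinned by the control-arm grid search, once per sex."""
    return {sex: m.calibrate_start_age(params, sex) for sex in ("men", "women")}


@pytest.fixture()
def zero_rate_params(params):
    """A copy with every transition probability zeroed: the cohort stays
    at risk forever (useful for closed-form checks)."""
    p = params.copy()
    for sex in ("men", "women"):
        for q in p.epidemiology.values[sex]:
            p.epidemiology.values[sex][q] = p.epidemiology.values[sex][q] * 0.0
    return p
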