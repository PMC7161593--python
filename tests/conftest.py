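import pytest

import msmcumexp as mx


@pytest.fixture(scope="session")
def twowave_config():
    return mx.load_preset("twowave")


@pytest.fixture(scope="session")
def confounded_config():
    return mx.load_preset("confounded")


@pytest.fixture(scope="session")
def survey_cohort():
    """Small full-realism cohort (attrition, non-response, exclusions)."""
    from dataclasses import replace
    config = replace(mx.load_preset("survey"), n=300)
    cohort, truth = mx.simulate_cohort(config, seed=5)
    return config, cohort, truth


@pytest.fixture(scope="session")
def twowave_cohort(twowave_config):
    from dataclasses import replace
    config = replace(twowave_config, n=400)
    cohort, truth = mx.simulate_cohort(config, seed=9)
    return config, cohort, truth
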