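import pytest

from pamcai.simulate import default_pilot_config, generate_cohort


@pytest.fixture(scope="session")
def pilot_cohort():
    """A pilot-sized synthetic cohort (10 per arm) at the default settings."""
    return generate_cohort(default_pilot_config(seed=20260928))


@pytest.fixture(scope="session")
def large_cohort():
    """A 500-per-arm cohort for parameter-recovery checks."""
    return generate_cohort(default_pilot_config(seed=11, n_per_arm=500))
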