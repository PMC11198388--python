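import numpy as np
import pytest

import survstrat as ss


@pytest.fixture(scope="session")
def default_cohort():
    """A mid-sized cohort from the calibrated generator defaults."""
    spec = ss.default_generator_spec(n=1317, seed=7)
    return spec, ss.generate_cohort(spec)


@pytest.fixture(scope="session")
def default_cohort_survival(default_cohort):
    _, cohort = default_cohort
    return ss.SurvivalData(
        cohort["time_years"].to_numpy(), cohort["event"].to_numpy()
    )


def random_censored_sample(rng, n):
    """Exponential survival with uniform censoring, as arrays."""
    t = rng.exponential(2.0, n)
    c = rng.uniform(0.1, 6.0, n)
    time = np.minimum(t, c)
    event = (t <= c).astype(int)
    return np.maximum(time, 1e-6), event
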