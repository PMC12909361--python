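import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def case1_data():
    """One simulated proof-of-concept cohort under the default study
    conditions (30 subjects, 300 mg IV bolus, 6 sampling times)."""
    import dpinns as dp
    cohort, agg = dp.simulate_onecomp_cohort(seed=1)
    return cohort, agg


@pytest.fixture(scope="session")
def case1_truth():
    ke = np.log(2.0) / 6.0
    return {"Vd_mean": 15.0, "Vd_sd": 1.5, "ke_mean": ke,
            "ke_sd": 0.4 * ke, "sigma": 0.1}
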