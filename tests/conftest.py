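import pytest
from hypothesis import HealthCheck, settings

import ddiquant as dq

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=60,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def fixtures():
    return dq.load_fixtures()


@pytest.fixture(scope="session")
def param_table():
    return dq.fixture_parameter_table()


@pytest.fixture()
def probe_studies():
    """Tiny anchored network: probe substrate against one inhibitor and one inducer."""
    return [
        dq.InteractionStudy(
            victim="midazolam",
            perpetrator="ritonavir",
            mechanism="mechanism_based_inhibition",
            auc_ratio_observed=16.67,
            cv=0.3,
            n_subjects=12,
            reference="probe-study-1",
        ),
        dq.InteractionStudy(
            victim="midazolam",
            perpetrator="etravirine",
            mechanism="induction",
            auc_ratio_observed=0.352,
            cv=0.25,
            n_subjects=16,
            reference="probe-study-2",
        ),
        dq.InteractionStudy(
            victim="amlodipine",
            perpetrator="ritonavir",
            mechanism="mechanism_based_inhibition",
            auc_ratio_observed=1.88,
            cv=0.3,
            n_subjects=10,
            reference="amlodipine-study",
        ),
    ]
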