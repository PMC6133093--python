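import numpy as np
import pytest

from revivalpred import CohortConfig, RevivalParams, Subject, generate_cohort


@pytest.fixture(scope="session")
def default_params():
    return RevivalParams()


@pytest.fixture(scope="session")
def small_cohort():
    """300 subjects under the default configuration (shared, read-only)."""
    return generate_cohort(CohortConfig(n_subjects=300, seed=11))


def make_subject(
    sid="X0",
    arm="control",
    observed_time=5.0,
    event=True,
    times=(0.0, 1.0),
    values=(70.0, 68.0),
    **kw,
):
    return Subject(
        id=sid,
        arm=arm,
        observed_time=observed_time,
        event=event,
        measurement_times=np.asarray(times, dtype=float),
        biomarker_values=np.asarray(values, dtype=float),
        **kw,
    )
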