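import numpy as np
import pytest

from msdamage import (
    Cohort,
    PatientRecord,
    SynthConfig,
    Visit,
    generate_cohort,
)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def make_patient(pid, times, edss, bv=None, subtype="unknown", age=None):
    bvs = bv if bv is not None else [None] * len(times)
    return PatientRecord(
        patient_id=pid,
        visits=[Visit(time=t, edss=e, bv=b) for t, e, b in zip(times, edss, bvs)],
        subtype=subtype,
        age_onset=age,
    )


@pytest.fixture
def small_cohort():
    return Cohort(
        patients=[
            make_patient("p1", [0, 6, 12, 24], [1.0, 1.5, 2.0, 2.0], subtype="RRMS", age=25.0),
            make_patient("p2", [0, 12, 24], [2.0, 3.0, 4.5], subtype="SPMS", age=35.0),
            make_patient("p3", [0, 6, 18, 24], [0.0, 0.5, 1.0, 1.5], subtype="PPMS", age=45.0),
        ],
        label="toy",
    )


@pytest.fixture(scope="session")
def stochastic_cohort():
    """A 4-archetype cohort with full stochastic heterogeneity."""
    return generate_cohort(SynthConfig(n_patients=48, seed=12))


@pytest.fixture(scope="session")
def curve_cohort():
    """A 4-archetype cohort under archetype-curve conditions (shared attack
    schedules, common onset age), where within-group spread is observational."""
    return generate_cohort(
        SynthConfig(n_patients=48, seed=12, deterministic_trains=True, age_onset_sd=0.0)
    )
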