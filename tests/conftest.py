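import numpy as np
import pytest

from recip import Cohort, PatientRecord, cohort_from_arrays


def make_record(pid="p1", baseline=100.0, interim=70.0, calls=(0, 0, 0),
                psa_b=100.0, psa_i=60.0, t=12.0, event=1, consensus=None):
    return PatientRecord(
        patient_id=pid,
        baseline_vol=baseline,
        interim_vol=interim,
        reader_calls=tuple(calls),
        psa_baseline=psa_b,
        psa_interim=psa_i,
        os_months=t,
        os_event=event,
        consensus_new_lesion=consensus,
    )


@pytest.fixture
def small_cohort():
    return Cohort(
        records=[
            make_record("a", 100, 60, (0, 0, 1), 100, 40, 20, 1),
            make_record("b", 80, 120, (1, 1, 1), 50, 80, 6, 1),
            make_record("c", 150, 150, (0, 0, 0), 200, 190, 15, 0),
        ]
    )


def random_survival_cohort(rng, n, max_time=10, tie_prone=True):
    """Small random right-censored sample with integer times (tie-prone)."""
    if tie_prone:
        times = rng.integers(1, max_time, n).astype(float)
    else:
        times = rng.uniform(0.5, max_time, n)
    events = rng.integers(0, 2, n)
    if events.sum() == 0:
        events[rng.integers(n)] = 1
    return times, events
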