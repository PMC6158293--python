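import numpy as np
import pytest

from patternsurv.cohort import CohortParams, PatientRecord, RawVisit, generate_cohort
from patternsurv.encoding import Event, Visit


def make_visit(pid, day, *items):
    """Visit from 'variable=state' strings."""
    return Visit(pid, day, frozenset(Event.parse(s) for s in items))


def make_record(pid="P0", sex="male", deceased=True, outcome_day=400, visits=None,
                **cov):
    defaults = dict(ethnicity="white", mgmt_status="unmethylated",
                    tumor_location="frontal_lobe", laterality="right",
                    initial_age=55.0)
    defaults.update(cov)
    return PatientRecord(patient_id=pid, sex=sex, deceased=deceased,
                         outcome_day=outcome_day, visits=visits or [], **defaults)


def simple_raw_visits(days, kps=None, volumes=None):
    kps = kps or [80] * len(days)
    volumes = volumes or [5000.0] * len(days)
    return [
        RawVisit(day=d, kps=k, mental_status=0, neurologic_function=1,
                 overall_neuro_status=0, volume_mm3=v)
        for d, k, v in zip(days, kps, volumes)
    ]


def random_sequence_db(rng, max_patients=5, max_visits=5, n_items=6):
    """Small random visit-sequence database for miner/oracle comparisons."""
    alphabet = [Event(f"v{i % 3}", f"s{i}") for i in range(n_items)]
    n_patients = rng.integers(1, max_patients + 1)
    db = {}
    for p in range(n_patients):
        n_visits = rng.integers(1, max_visits + 1)
        day = 0
        visits = []
        for _ in range(n_visits):
            k = rng.integers(1, 4)
            items = rng.choice(len(alphabet), size=k, replace=False)
            # at most one item per variable within a visit
            chosen = {}
            for i in items:
                chosen[alphabet[i].variable] = alphabet[i]
            visits.append(Visit(f"p{p}", day, frozenset(chosen.values())))
            day += int(rng.integers(10, 50))
        db[f"p{p}"] = visits
    return db


@pytest.fixture(scope="session")
def default_cohort():
    return generate_cohort(CohortParams(seed=7))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
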