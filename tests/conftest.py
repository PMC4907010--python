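from datetime import datetime, timedelta

import numpy as np
import pytest

from edcrowd import PatientRecord, SimulationSpec, default_roster, simulate_ed


def make_record(visit_id, arrival, stay_min, triage=None, first=None, last=None, **kw):
    """Build a record from an arrival and minute offsets into the stay."""
    dep = arrival + timedelta(minutes=stay_min)
    off = lambda m: None if m is None else arrival + timedelta(minutes=m)
    return PatientRecord(
        visit_id=visit_id, arrival=arrival, departure=dep,
        triage_time=off(triage), first_ews_time=off(first), last_ews_time=off(last), **kw
    )


def random_records(rng, n, period_start, period_minutes, max_stay_min=600):
    """n records with arrivals inside the period, at minute precision."""
    arr_off = rng.integers(0, period_minutes, n)
    stays = rng.integers(0, max_stay_min, n)
    return [
        make_record(f"r{i}", period_start + timedelta(minutes=int(a)), int(s))
        for i, (a, s) in enumerate(zip(arr_off, stays))
    ]


@pytest.fixture(scope="session")
def roster():
    return default_roster()


@pytest.fixture(scope="session")
def simulated_month():
    """One month of synthetic visits at the default study conditions."""
    spec = SimulationSpec(
        period_start=datetime(2013, 3, 1, 7, 0),
        period_end=datetime(2013, 3, 31, 7, 0),
        seed=20130301,
    )
    return simulate_ed(spec), spec


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
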