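import dataclasses
import datetime as dt

import numpy as np
import pytest
from hypothesis import settings

from bomarisk.study_io import BomaRecord, PriceTable, VisitRecord
from bomarisk.synthetic import default_config, simulate_study

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None,
                          database=None)
settings.load_profile("suite")


def make_boma(boma_id="B1", pair_id="P1", arm="control", village="Selela",
              lon=36.0, lat=-3.8, circ=50.0, cost=None, date=dt.date(2010, 1, 1)):
    return BomaRecord(boma_id, pair_id, arm, village, lon, lat, circ, cost, date)


def make_visit(boma_id="B1", date=dt.date(2010, 6, 30), hyena_attempts=0,
               hyena_successes=0, **counts):
    attempts = {"spotted_hyena": hyena_attempts}
    successes = {"spotted_hyena": hyena_successes}
    for key, val in counts.items():
        kind, species = key.split("__")
        (attempts if kind == "attempts" else successes)[species] = val
    return VisitRecord(boma_id, date, 30, attempts, successes, {})


@pytest.fixture(scope="session")
def default_study():
    """One default synthetic study (45 pairs, 1,152 revisits)."""
    return simulate_study(default_config(seed=20090101))


@pytest.fixture(scope="session")
def replicate_studies():
    """Twenty default-config studies with distinct sub-seeds, for calibration
    checks that must average over the village/year random effects."""
    cfg = default_config()
    seeds = np.random.SeedSequence(77).generate_state(20) % (2**31)
    return [simulate_study(dataclasses.replace(cfg, seed=int(s))) for s in seeds]


@pytest.fixture
def prices():
    return PriceTable({"cattle_adult": 364.0, "cattle_juv": 157.0,
                       "donkey_adult": 80.0, "shoat_adult": 42.0, "shoat_juv": 42.0})
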