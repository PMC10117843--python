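"""Shared fixtures: small synthetic cohorts and hand-built risk sets."""

from __future__ import annotations

from datetime import date

import pytest

from occohort.persontime import CategorySpec, ExposureHistory
from occohort.cohort import WorkerRecord
from occohort.risksets import RiskSet
from occohort.synthetic import SimConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """200-worker synthetic cohort used across unit tests."""
    return generate_cohort(SimConfig(n_workers=200, seed=7))


@pytest.fixture(scope="session")
def medium_cohort():
    """2,000-worker cohort for oracle-equivalence and SMR tests."""
    return generate_cohort(SimConfig(n_workers=2000, seed=11))


@pytest.fixture
def default_spec():
    return CategorySpec()


def make_worker(worker_id="W1", birth=date(1930, 6, 15), hire=date(1955, 3, 1),
                term=date(1970, 3, 1), segments=(), dead=None, cause=None,
                plant=1, race="white", sex="male", pay="wage", smoker=0):
    return WorkerRecord(
        worker_id=worker_id, plant=plant, race=race, sex=sex, pay_type=pay,
        birth_date=birth, hire_date=hire, termination_date=term,
        exposure=ExposureHistory(tuple(segments)), ever_smoker=smoker,
        vital_status="dead" if dead else "alive", death_date=dead, cause=cause)


def make_risk_set(k: int, case_exposure, control_exposures,
                  covs=None) -> RiskSet:
    """Hand-built risk set; exposures are (category, cumulative) or scalars."""
    def unpack(e):
        if isinstance(e, tuple):
            return int(e[0]), float(e[1]), 0.0
        return (1 if e > 0 else 0), float(e), 0.0

    ids = [f"s{k}case"] + [f"s{k}ctl{j}" for j in range(len(control_exposures))]
    expo = {ids[0]: unpack(case_exposure)}
    for j, e in enumerate(control_exposures):
        expo[ids[j + 1]] = unpack(e)
    cov = {i: (covs or {}).get(i, ("white", "male", "wage")) for i in ids}
    return RiskSet(case_id=ids[0], event_date=date(2000, 1, 1), event_age=60.0,
                   control_ids=ids[1:], exposure_at_event=expo, covariates=cov)
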