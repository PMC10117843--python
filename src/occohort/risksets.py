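"""Nested case-control risk sets matched on exact attained age at death.

For each death from the index cause, the risk set contains the case plus
every cohort member still under follow-up at the case's exact attained age
(in days) whose year of birth lies within a caliper of the case's.  This is
incidence-density sampling with age as the time scale: a member who later
dies of the index cause serves as a control in earlier risk sets but never
after their own death, and two cases dying at exactly the same attained age
are not controls for each other.  Time-dependent exposures are evaluated at
the calendar date each member attains the case's event age, with the
configured lag.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date

import numpy as np
import pandas as pd

from .cohort import WorkerRecord
from .persontime import (CategorySpec, average_intensity, classify,
                         cumulative_exposure)

DEFAULT_FOLLOW_UP = (date(1942, 1, 1), date(2011, 12, 31))


@dataclass
class RiskSet:
    case_id: str
    event_date: date
    event_age: float              # exact attained age, years (days / 365.25)
    control_ids: list[str]
    #: worker id -> (category index, cumulative ppm-years, average intensity ppm)
    exposure_at_event: dict[str, tuple[int, float, float]]
    #: worker id -> (race, sex, pay_type)
    covariates: dict[str, tuple[str, str, str]]
    excluded: bool = False        # no eligible controls


def build_risk_sets(cohort: list[WorkerRecord], cause: str,
                    spec: CategorySpec | None = None,
                    caliper: float = 1.0,
                    follow_up: tuple[date, date] = DEFAULT_FOLLOW_UP) -> list[RiskSet]:
    """One risk set per death from ``cause``, deterministically ordered.

    Sets with zero eligible controls are returned with ``excluded=True``
    and are dropped by the model-fitting stage.
    """
    spec = spec or CategorySpec()
    fu_start, fu_end = follow_up
    fu_start_ord, fu_end_ord = fu_start.toordinal(), fu_end.toordinal()

    workers = sorted(cohort, key=lambda w: w.worker_id)
    n = len(workers)
    birth = np.array([w.birth_date.toordinal() for w in workers])
    birth_year = np.array([w.birth_date.year for w in workers])
    entry = np.array([max(w.hire_date.toordinal(), fu_start_ord) for w in workers])
    death_ord = np.array([w.death_date.toordinal() if w.death_date else -1 for w in workers])
    is_dead = np.array([w.vital_status == "dead" for w in workers])
    exit_ = np.where(is_dead & (death_ord <= fu_end_ord), death_ord, fu_end_ord)
    dies_of_cause = is_dead & np.array([w.cause == cause for w in workers])

    case_order = sorted(
        (i for i in range(n)
         if dies_of_cause[i] and fu_start_ord <= death_ord[i] <= fu_end_ord),
        key=lambda i: (death_ord[i], workers[i].worker_id))
    if not case_order:
        raise ValueError(f"no deaths from cause {cause!r} within follow-up")

    sets: list[RiskSet] = []
    for ci in case_order:
        age_days = death_ord[ci] - birth[ci]
        attain = birth + age_days  # date each member reaches the case's age
        at_risk = (attain >= entry) & (
            (attain < exit_)
            | ((attain == exit_) & ~(dies_of_cause & (death_ord == attain))))
        eligible = at_risk & (np.abs(birth_year - birth_year[ci]) <= caliper)
        eligible[ci] = False
        controls = np.flatnonzero(eligible)

        members = [ci, *controls]
        expo: dict[str, tuple[int, float, float]] = {}
        cov: dict[str, tuple[str, str, str]] = {}
        for j in members:
            w = workers[j]
            at = date.fromordinal(int(attain[j]))
            cum = cumulative_exposure(w.exposure, at, spec.lag)
            aie = average_intensity(w.exposure, at, spec.lag)
            value = cum if spec.kind == "cumulative" else aie
            cat = classify(value, spec, ever_exposed=cum > 0)
            expo[w.worker_id] = (cat, cum, aie)
            cov[w.worker_id] = (w.race, w.sex, w.pay_type)
        sets.append(RiskSet(
            case_id=workers[ci].worker_id,
            event_date=workers[ci].death_date,
            event_age=age_days / 365.25,
            control_ids=[workers[j].worker_id for j in controls],
            exposure_at_event=expo,
            covariates=cov,
            excluded=len(controls) == 0,
        ))
    return sets


def risk_sets_to_frame(sets: list[RiskSet]) -> pd.DataFrame:
    """Audit TSV layout: one row per risk-set member."""
    rows = []
    for k, rs in enumerate(sets):
        for wid in (rs.case_id, *rs.control_ids):
            cat, cum, aie = rs.exposure_at_event[wid]
            race, sex, pay = rs.covariates[wid]
            rows.append({"set": k, "role": "case" if wid == rs.case_id else "control",
                         "worker_id": wid, "event_age": round(rs.event_age, 4),
                         "category": cat, "cumulative": round(cum, 6),
                         "aie": round(aie, 6), "race": race, "sex": sex,
                         "pay_type": pay, "excluded": rs.excluded})
    return pd.DataFrame(rows)


def sample_controls(sets: list[RiskSet], m: int, seed: int = 0) -> list[RiskSet]:
    """Seeded m:1 control sampling for speed on large cohorts.

    Sets with m or fewer controls are kept whole; sampling preserves the
    incidence-density structure because controls are drawn uniformly
    within each risk set.
    """
    if m < 1:
        raise ValueError("m must be at least 1")
    rng = np.random.default_rng(seed)
    out = []
    for rs in sets:
        if len(rs.control_ids) <= m:
            out.append(rs)
            continue
        keep = sorted(rng.choice(len(rs.control_ids), size=m, replace=False))
        ids = [rs.control_ids[i] for i in keep]
        members = [rs.case_id, *ids]
        out.append(RiskSet(
            case_id=rs.case_id, event_date=rs.event_date, event_age=rs.event_age,
            control_ids=ids,
            exposure_at_event={i: rs.exposure_at_event[i] for i in members},
            covariates={i: rs.covariates[i] for i in members},
            excluded=rs.excluded))
    return out
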