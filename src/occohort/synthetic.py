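"""Synthetic multi-plant occupational cohorts with known confounding.

The generator emulates the structure of a large (historically ~25k-worker,
eight-plant) acrylonitrile-production cohort hired from 1942 onward and
followed for mortality through 2011: per-plant ever-smoking prevalences
between 0.53 and 0.78, a strong smoking effect on lung cancer (RR 19.1) and
COPD, a weaker one on bladder cancer (RR 3.5), an optional
asbestos-confounded plant emulating shipyard co-exposure, and a
configurable-through-the-config true exposure effect whose default is the
null.  Deaths arise from a yearly discrete-time competing-risks draw from
cause-specific hazards

    hazard(cause, t) = baseline(cause, stratum(t))
                       * rr_smoking^smoker * rr_asbestos^asbestos
                       * an_effect(category(t))

so that every downstream stage (person-time, SMRs, risk sets, rate-ratio
models, confounding adjustment) can be exercised against a known truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import date

import numpy as np

from .cohort import CAUSES, WorkerRecord
from .persontime import (CUMULATIVE_CUTPOINTS, AGE_STARTS, PERIOD_STARTS,
                         CategorySpec, ExposureHistory, date_from_year_frac, year_frac)
from .rates import ReferenceRateTable, RACES, SEXES

#: Per-plant ever-smoking prevalence among workers (range 0.53-0.78).
DEFAULT_PLANT_SMOKING = (0.71, 0.53, 0.62, 0.78, 0.71, 0.68, 0.67, 0.65)

# Never-smoker baseline rates per person-year at age band 60-64 and the
# per-year-of-age log-slope of the Gompertz-like age trend.  Relative
# magnitudes follow the cause mix of mid-century US industrial cohorts;
# the lung and COPD levels are enriched so that a 5,000-worker cohort
# yields event counts adequate for stable risk-set estimation (matching
# any real cohort's absolute death counts is a non-goal).
_BASE_60 = {"lung": 3.75e-4, "bladder": 2.0e-5, "mesothelioma": 1.0e-5,
            "pneumonitis": 3.0e-5, "copd": 3.2e-4, "other": 1.2e-2}
# COPD's baseline is proportional to lung cancer's (same age shape and
# covariate multipliers): the negative-control recovery scenario assumes
# exact equi-confounding, which for event-time-evaluated exposures requires
# the two outcomes to share their event-age distribution up to a constant.
_AGE_SLOPE = {"lung": 0.069, "bladder": 0.069, "mesothelioma": 0.055,
              "pneumonitis": 0.080, "copd": 0.069, "other": 0.085}
_FEMALE_MULT = {"lung": 0.5, "bladder": 0.3, "mesothelioma": 0.2,
                "pneumonitis": 0.8, "copd": 0.5, "other": 0.6}
_NONWHITE_MULT = {"lung": 1.0, "bladder": 0.9, "mesothelioma": 0.8,
                  "pneumonitis": 1.2, "copd": 1.0, "other": 1.15}


class ConfigurationError(ValueError):
    pass


@dataclass
class SimConfig:
    """Study conditions for the synthetic cohort.

    Defaults are the emulated study conditions: null exposure effect,
    equi-confounding by smoking (the smoking effect on the negative-control
    outcome COPD equals its effect on lung cancer), and no
    exposure-smoking association unless ``smoker_exposed_prob`` is set.
    """

    n_workers: int = 5000
    n_plants: int = 8
    hire_year_range: tuple[int, int] = (1942, 1990)
    study_end: date = date(2011, 12, 31)
    plant_smoking_prevalence: tuple[float, ...] = DEFAULT_PLANT_SMOKING
    rr_smoking_lung: float = 19.1
    rr_smoking_copd: float = 19.1
    rr_smoking_bladder: float = 3.5
    asbestos_plant_index: int | None = None
    rr_asbestos_lung: float = 3.5
    rr_asbestos_mesothelioma: float = 10.0
    #: P(asbestos) within the flagged plant, by AN-exposure status.
    asbestos_prev_exposed: float = 0.8
    asbestos_prev_unexposed: float = 0.1
    #: multiplicative lung-hazard effect per exposed category (null default)
    an_effect_lung: tuple[float, ...] | None = None
    #: overall fraction of workers holding AN-exposed jobs
    exposed_fraction: float = 0.65
    #: mixing parameter: P(exposed job | ever-smoker); None = no association
    smoker_exposed_prob: float | None = None
    #: second mixing knob: intensity scale for smokers' exposed jobs (1 = none)
    smoker_intensity_multiplier: float = 1.0
    exposure_intensity_median: float = 0.25  # ppm, lognormal
    exposure_intensity_sigma: float = 1.3
    employment_duration_median: float = 6.0  # years, lognormal
    employment_duration_sigma: float = 0.9
    exposure_delay_mean: float = 2.0  # years from hire to first exposed job
    prop_male: float = 0.85
    prop_white: float = 0.85
    prop_wage: float = 0.70
    hire_age_mean: float = 27.0
    hire_age_sd: float = 6.0
    reference_smoking_prevalence: float = 0.271
    category_spec: CategorySpec = field(default_factory=CategorySpec)
    baseline_rates: ReferenceRateTable | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_workers <= 0:
            raise ConfigurationError("n_workers must be positive")
        if self.n_plants <= 0 or len(self.plant_smoking_prevalence) < self.n_plants:
            raise ConfigurationError("need a smoking prevalence per plant")
        probs = (*self.plant_smoking_prevalence, self.exposed_fraction,
                 self.reference_smoking_prevalence,
                 self.asbestos_prev_exposed, self.asbestos_prev_unexposed)
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise ConfigurationError("all prevalences must lie in [0, 1]")
        if self.smoker_exposed_prob is not None and not (0 <= self.smoker_exposed_prob <= 1):
            raise ConfigurationError("smoker_exposed_prob must lie in [0, 1]")
        if self.smoker_intensity_multiplier <= 0:
            raise ConfigurationError("smoker_intensity_multiplier must be positive")
        ratios = (self.rr_smoking_lung, self.rr_smoking_copd, self.rr_smoking_bladder,
                  self.rr_asbestos_lung, self.rr_asbestos_mesothelioma)
        if any(r <= 0 for r in ratios):
            raise ConfigurationError("all rate ratios must be positive")
        y0, y1 = self.hire_year_range
        if not (1942 <= y0 <= y1 <= self.study_end.year):
            raise ConfigurationError("hire years must lie in [1942, study end]")
        if self.an_effect_lung is not None:
            k = len(self.category_spec.cutpoints) + 1
            if len(self.an_effect_lung) != k or any(r <= 0 for r in self.an_effect_lung):
                raise ConfigurationError(f"an_effect_lung needs {k} positive ratios")
        if self.baseline_rates is not None and len(self.baseline_rates.causes) == 0:
            raise ConfigurationError("baseline_rates has no causes")


def never_smoker_baseline(config: SimConfig) -> ReferenceRateTable:
    """Cause-specific never-smoker / unexposed baseline hazard table."""
    shape = (len(CAUSES), len(RACES), len(SEXES), len(AGE_STARTS), len(PERIOD_STARTS))
    values = np.zeros(shape)
    age_mid = np.array([a + 2.5 for a in AGE_STARTS])
    for ci, cause in enumerate(CAUSES):
        age_curve = _BASE_60[cause] * np.exp(_AGE_SLOPE[cause] * (age_mid - 62.5))
        for ri, race in enumerate(RACES):
            for si, sex in enumerate(SEXES):
                mult = (_FEMALE_MULT[cause] if sex == "female" else 1.0)
                mult *= (_NONWHITE_MULT[cause] if race == "nonwhite" else 1.0)
                values[ci, ri, si, :, :] = (mult * age_curve)[:, None]
    return ReferenceRateTable(label="baseline-never-smoker", values=values)


def generate_reference_rates(config: SimConfig) -> ReferenceRateTable:
    """Reference-population rate table matching the generated cohort.

    The population mixes never smokers and ever smokers at the standard
    population prevalence, so external comparisons against this table are
    confounded exactly when the cohort's smoking prevalence differs from
    ``reference_smoking_prevalence``.  Rates are strictly positive for every
    cause in use and cover every age/period stratum of the follow-up window.
    """
    base = never_smoker_baseline(config)
    p0 = config.reference_smoking_prevalence
    mult = {"lung": 1 + (config.rr_smoking_lung - 1) * p0,
            "copd": 1 + (config.rr_smoking_copd - 1) * p0,
            "bladder": 1 + (config.rr_smoking_bladder - 1) * p0}
    values = base.values.copy()
    for cause, m in mult.items():
        values[base.cause_index(cause)] *= m
    return ReferenceRateTable(label="reference-population", values=values)


def _lookup(table: ReferenceRateTable, cause_idx: int, race_idx, sex_idx, age_idx, period_idx):
    return table.values[cause_idx, race_idx, sex_idx, age_idx, period_idx]


def generate_cohort(config: SimConfig) -> list[WorkerRecord]:
    """Draw a cohort; deterministic given ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    n = config.n_workers
    base = config.baseline_rates if config.baseline_rates is not None else never_smoker_baseline(config)
    for cause in ("lung", "copd", "bladder", "mesothelioma", "pneumonitis", "other"):
        base.cause_index(cause)  # raises ConfigurationError-ish if absent

    plant = rng.integers(0, config.n_plants, size=n)
    sex_idx = (rng.random(n) >= config.prop_male).astype(int)   # 0 male, 1 female
    race_idx = (rng.random(n) >= config.prop_white).astype(int)  # 0 white, 1 nonwhite
    wage = rng.random(n) < config.prop_wage
    prev = np.asarray(config.plant_smoking_prevalence)[plant]
    smoker = rng.random(n) < prev

    f = config.exposed_fraction
    if config.smoker_exposed_prob is None:
        p_exp = np.full(n, f)
    else:
        m = config.smoker_exposed_prob
        p_nonsmoker = np.clip((f - prev * m) / np.maximum(1 - prev, 1e-12), 0.0, 1.0)
        p_exp = np.where(smoker, m, p_nonsmoker)
    exposed = rng.random(n) < p_exp

    y0, y1 = config.hire_year_range
    hire_yf = rng.integers(y0, y1 + 1, size=n) + rng.random(n) * 0.995
    hire_age = np.clip(rng.normal(config.hire_age_mean, config.hire_age_sd, size=n), 18.0, 55.0)
    birth_yf = hire_yf - hire_age
    dur = rng.lognormal(math.log(config.employment_duration_median),
                        config.employment_duration_sigma, size=n)
    study_end_yf = year_frac(config.study_end)
    term_yf = np.minimum(hire_yf + np.maximum(dur, 0.02), study_end_yf)

    delay = rng.exponential(config.exposure_delay_mean, size=n)
    seg_start = np.minimum(hire_yf + delay, term_yf)
    intensity = rng.lognormal(math.log(config.exposure_intensity_median),
                              config.exposure_intensity_sigma, size=n)
    if config.smoker_intensity_multiplier != 1.0:
        intensity = np.where(smoker, intensity * config.smoker_intensity_multiplier,
                             intensity)

    asbestos = np.zeros(n, dtype=bool)
    if config.asbestos_plant_index is not None:
        in_plant = plant == config.asbestos_plant_index
        p_asb = np.where(exposed, config.asbestos_prev_exposed, config.asbestos_prev_unexposed)
        asbestos = in_plant & (rng.random(n) < p_asb)

    lag = config.category_spec.lag
    cutpoints = np.asarray(config.category_spec.cutpoints)
    an_eff = None if config.an_effect_lung is None else np.asarray(config.an_effect_lung)

    cause_order = ("lung", "copd", "bladder", "mesothelioma", "pneumonitis", "other")
    cidx = {c: base.cause_index(c) for c in cause_order}
    smoking_mult = {"lung": config.rr_smoking_lung, "copd": config.rr_smoking_copd,
                    "bladder": config.rr_smoking_bladder}

    death_yf = np.full(n, np.inf)
    death_cause = np.full(n, -1, dtype=int)
    period_first = base.period_starts[0]
    n_age = len(base.age_starts)
    n_period = len(base.period_starts)

    for year in range(1942, config.study_end.year + 1):
        alive = ~np.isfinite(death_yf) & (hire_yf < year + 1)
        idx = np.flatnonzero(alive)
        if idx.size == 0:
            continue
        start = np.maximum(hire_yf[idx], float(year))
        frac = np.clip(year + 1.0 - start, 0.0, 1.0)
        age = (year + 0.5) - birth_yf[idx]
        ai = np.clip((age // 5).astype(int), 0, n_age - 1)
        pi = min(max((year - period_first) // 5, 0), n_period - 1)
        ri, si = race_idx[idx], sex_idx[idx]
        smk, asb, exp_ = smoker[idx], asbestos[idx], exposed[idx]

        hazards = np.empty((len(cause_order), idx.size))
        for k, cause in enumerate(cause_order):
            h = _lookup(base, cidx[cause], ri, si, ai, pi).copy()
            if cause in smoking_mult:
                h = h * np.where(smk, smoking_mult[cause], 1.0)
            if cause == "lung":
                h = h * np.where(asb, config.rr_asbestos_lung, 1.0)
                if an_eff is not None:
                    cum = intensity[idx] * np.clip(
                        np.minimum(term_yf[idx], year + 0.5 - lag) - seg_start[idx], 0.0, None)
                    cum = np.where(exp_, cum, 0.0)
                    cat = np.searchsorted(cutpoints, cum, side="left")
                    h = h * an_eff[cat]
            elif cause == "mesothelioma":
                h = h * np.where(asb, config.rr_asbestos_mesothelioma, 1.0)
            hazards[k] = h
        htot = hazards.sum(axis=0) * frac
        p_die = -np.expm1(-htot)
        u = rng.random(idx.size)
        dies = u < p_die
        if not dies.any():
            continue
        d = np.flatnonzero(dies)
        # cause draw proportional to cause-specific hazards
        hsub = hazards[:, d]
        cdf = np.cumsum(hsub / hsub.sum(axis=0, keepdims=True), axis=0)
        uc = rng.random(d.size)
        which = (uc[None, :] > cdf).sum(axis=0)
        t = start[d] + rng.random(d.size) * (year + 1.0 - start[d])
        death_yf[idx[d]] = np.minimum(t, study_end_yf)
        death_cause[idx[d]] = which

    workers: list[WorkerRecord] = []
    for i in range(n):
        birth = date_from_year_frac(birth_yf[i])
        hire = date_from_year_frac(hire_yf[i])
        dead = np.isfinite(death_yf[i])
        death = None
        if dead:
            death = date_from_year_frac(death_yf[i])
            if death <= hire:
                death = date.fromordinal(hire.toordinal() + 1)
        term = date_from_year_frac(term_yf[i])
        if dead and death < term:
            term = death
        if term <= hire:
            term = date.fromordinal(hire.toordinal() + 1)
        if dead and death < term:
            death = term
        segments = ()
        if exposed[i]:
            s0 = date_from_year_frac(seg_start[i])
            if s0 < hire:
                s0 = hire
            if s0 < term:
                segments = ((s0, term, float(intensity[i])),)
        workers.append(WorkerRecord(
            worker_id=f"W{i:06d}",
            plant=int(plant[i]) + 1,
            race=RACES[race_idx[i]],
            sex=SEXES[sex_idx[i]],
            pay_type="wage" if wage[i] else "salary",
            birth_date=birth,
            hire_date=hire,
            termination_date=term,
            exposure=ExposureHistory(segments),
            ever_smoker=int(smoker[i]),
            asbestos_exposed=int(asbestos[i]),
            vital_status="dead" if dead else "alive",
            death_date=death,
            cause=cause_order[death_cause[i]] if dead else None,
        ))
    return workers


def confounded_scenario(seed: int = 0, n_workers: int = 5000) -> SimConfig:
    """Null-exposure scenario with strong smoking-driven equi-confounding.

    Smokers are preferentially assigned to exposed jobs (mixing 0.9) and to
    jobs of higher intensity (x3), while the true exposure effect on every
    cause is null and smoking acts on lung cancer and COPD by the same
    factor.  The unadjusted exposed-vs-unexposed lung rate ratio is then
    biased well above 1 and the negative-control adjustment should recover
    the null.  A tighter intensity spread (lognormal sigma 0.6) keeps the
    continuous dose-response models stable at this cohort size.
    """
    return SimConfig(n_workers=n_workers, seed=seed, smoker_exposed_prob=0.9,
                     smoker_intensity_multiplier=3.0, exposure_intensity_sigma=0.6)


def asbestos_scenario(seed: int = 0, n_workers: int = 5000,
                      plant_index: int = 3) -> SimConfig:
    """Null-exposure scenario with one asbestos-confounded plant.

    Within the flagged plant, asbestos co-exposure is far more common in
    AN-exposed jobs (0.8 vs 0.1), confounding the exposed-vs-unexposed lung
    contrast the way shipyard-adjacent employment would; excluding the
    plant should lower the exposed lung rate ratio.
    """
    return SimConfig(n_workers=n_workers, seed=seed, asbestos_plant_index=plant_index)
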