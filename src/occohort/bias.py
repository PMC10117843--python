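"""Indirect SMR bias adjustment for an unmeasured binary confounder.

When a cohort's prevalence of a confounder (ever smoking, P1) differs from
the reference population's (P0), an external comparison is biased by the
confounding risk ratio

    CRR = (P1 (RR - 1) + 1) / (P0 (RR - 1) + 1),

where RR is the confounder-disease rate ratio; the adjusted SMR is
SMR / CRR.  A Monte Carlo sensitivity analysis propagates uncertainty in
(P1, P0, RR) — and optionally the SMR's own Poisson sampling error —
through the same formula to an interval on the adjusted SMR.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np


def confounding_risk_ratio(p1: float, p0: float, rr: float) -> float:
    """CRR from cohort prevalence p1, reference prevalence p0, and RR."""
    if not (0 <= p1 <= 1 and 0 <= p0 <= 1):
        raise ValueError("prevalences must lie in [0, 1]")
    if rr <= 0:
        raise ValueError("confounder-disease RR must be positive")
    return (p1 * (rr - 1) + 1) / (p0 * (rr - 1) + 1)


def adjust_smr(smr: float, crr: float) -> float:
    """Indirectly adjusted SMR = unadjusted SMR / CRR."""
    if crr <= 0:
        raise ValueError("CRR must be positive")
    return smr / crr


def inflate_prevalence(p_observed: float, factor: float) -> float:
    """Scale an observed prevalence by a correction factor, clipped at 1."""
    p = p_observed * factor
    if p > 1.0:
        warnings.warn(f"inflated prevalence {p:.3f} clipped to 1.0", stacklevel=2)
        return 1.0
    return p


def round_half_away(x: float, ndigits: int = 2) -> float:
    """Round half away from zero (the convention of printed two-decimal tables)."""
    factor = 10 ** ndigits
    return float(np.sign(x) * np.floor(abs(x) * factor + 0.5) / factor)


# ---------------------------------------------------------------------------
# priors

@dataclass(frozen=True)
class Prior:
    """Uncertainty distribution for a bias parameter.

    family: 'point', 'beta' (params a, b), or 'lognormal' (params mu, sigma
    on the log scale).
    """

    family: str
    params: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.family not in ("point", "beta", "lognormal"):
            raise ValueError(f"unknown prior family {self.family!r}")

    def draw(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.family == "point":
            return np.full(n, self.params[0])
        if self.family == "beta":
            return rng.beta(self.params[0], self.params[1], size=n)
        return rng.lognormal(self.params[0], self.params[1], size=n)


def beta_prior(mean: float, sd: float) -> Prior:
    """Moment-matched Beta prior for a prevalence."""
    if not (0 < mean < 1) or sd <= 0:
        raise ValueError("need 0 < mean < 1 and sd > 0")
    nu = mean * (1 - mean) / sd ** 2 - 1
    if nu <= 0:
        raise ValueError("sd too large for a Beta prior at this mean")
    return Prior("beta", (mean * nu, (1 - mean) * nu))


def lognormal_prior_from_ci(median: float, ci_low: float, ci_high: float) -> Prior:
    """Log-normal prior matched to a point estimate and 95% interval."""
    if not (0 < ci_low <= median <= ci_high):
        raise ValueError("need 0 < ci_low <= median <= ci_high")
    sigma = (np.log(ci_high) - np.log(ci_low)) / (2 * 1.959964)
    return Prior("lognormal", (float(np.log(median)), float(sigma)))


# ---------------------------------------------------------------------------
# Monte Carlo sensitivity analysis

@dataclass
class BiasParameters:
    """Point estimates and uncertainty distributions for indirect adjustment."""

    p_cohort: float
    p_reference: float
    rr_confounder: float
    inflation_factor: float = 1.0
    priors: dict[str, Prior] | None = None   # keys: p_cohort, p_reference, rr
    n_draws: int = 5000
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.p_cohort <= 1 and 0 <= self.p_reference <= 1):
            raise ValueError("prevalences must lie in [0, 1]")
        if self.rr_confounder <= 0 or self.inflation_factor <= 0:
            raise ValueError("ratios must be positive")
        if self.n_draws < 1:
            raise ValueError("n_draws must be at least 1")

    def prior(self, key: str, point: float) -> Prior:
        if self.priors and key in self.priors:
            return self.priors[key]
        return Prior("point", (point,))


@dataclass
class AdjustedSmr:
    smr_unadjusted: float
    crr: float
    smr_adjusted: float
    mc_interval: tuple[float, float] | None = None
    n_rejected: int = 0


def mc_sensitivity(params: BiasParameters, smr: float,
                   observed: int | None = None,
                   include_smr_uncertainty: bool = True) -> AdjustedSmr:
    """Monte Carlo interval on the indirectly adjusted SMR.

    Each draw samples (P1, P0, RR) from the priors (invalid prevalence or
    ratio draws are rejected and redrawn, counted in ``n_rejected``),
    applies the prevalence inflation factor, recomputes the CRR, and divides
    the SMR — itself redrawn from its Poisson (gamma) sampling distribution
    when ``observed`` is given and ``include_smr_uncertainty`` is set —
    to obtain the 2.5th/97.5th percentile interval.  Deterministic given
    ``params.seed``.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_draws
    p1_prior = params.prior("p_cohort", params.p_cohort)
    p0_prior = params.prior("p_reference", params.p_reference)
    rr_prior = params.prior("rr", params.rr_confounder)

    def draw_valid(prior: Prior, valid) -> tuple[np.ndarray, int]:
        x = prior.draw(rng, n)
        rejected = 0
        for _ in range(100):
            bad = ~valid(x)
            if not bad.any():
                break
            rejected += int(bad.sum())
            x[bad] = prior.draw(rng, int(bad.sum()))
        return x, rejected

    p1, r1 = draw_valid(p1_prior, lambda x: (x >= 0) & (x <= 1))
    p0, r0 = draw_valid(p0_prior, lambda x: (x >= 0) & (x <= 1))
    rr, r2 = draw_valid(rr_prior, lambda x: x > 0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        p1 = np.clip(p1 * params.inflation_factor, 0.0, 1.0)
    crr_draws = (p1 * (rr - 1) + 1) / (p0 * (rr - 1) + 1)

    if observed is not None and include_smr_uncertainty and observed > 0 and smr > 0:
        expected = observed / smr
        smr_draws = rng.gamma(observed, 1.0, size=n) / expected
    else:
        smr_draws = np.full(n, smr)
    adj = smr_draws / crr_draws
    lo, hi = np.percentile(adj, [2.5, 97.5])

    p1_point = inflate_prevalence(params.p_cohort, params.inflation_factor)
    crr = confounding_risk_ratio(p1_point, params.p_reference, params.rr_confounder)
    return AdjustedSmr(smr_unadjusted=smr, crr=crr, smr_adjusted=adjust_smr(smr, crr),
                       mc_interval=(float(lo), float(hi)),
                       n_rejected=r0 + r1 + r2)
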