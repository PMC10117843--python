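"""Rate-ratio estimation from risk sets by conditional likelihood.

With one case per risk set the exact conditional-logistic and Cox partial
likelihoods coincide: the contribution of set g is

    exp(x_case' beta) / sum_{j in g} exp(x_j' beta),

a concave softmax likelihood maximised by Newton-Raphson with step-halving
from beta = 0.  Variances come from the inverse observed information.
Terms with no within-set variation are reported as non-identifiable rather
than fitted; complete separation is flagged with an infinite bound instead
of crashing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .risksets import RiskSet

_Z = stats.norm.ppf(0.975)


@dataclass
class RateRatioEstimate:
    """A fitted log rate ratio and its Wald interval on the ratio scale."""

    term: str
    beta: float
    variance: float
    identifiable: bool = True
    separated: bool = False

    @property
    def rr(self) -> float:
        return float(np.exp(self.beta))

    @property
    def se(self) -> float:
        return float(np.sqrt(self.variance))

    @property
    def ci_low(self) -> float:
        if self.separated or not self.identifiable:
            return 0.0
        return float(np.exp(self.beta - _Z * self.se))

    @property
    def ci_high(self) -> float:
        if self.separated or not self.identifiable:
            return float("inf")
        return float(np.exp(self.beta + _Z * self.se))


@dataclass
class DoseResponseModel:
    """Log-linear-quadratic dose response: RR(x) = exp(b1 x + b2 x^2).

    RR(0) = 1 by construction.  ``scale`` names the exposure units so that
    adjustment only combines models on the same scale.
    """

    beta1: float
    beta2: float
    covariance: np.ndarray
    scale: str = "ppm-years"
    identifiable: bool = True
    separated: bool = False

    def rr(self, x) -> np.ndarray | float:
        x = np.asarray(x, dtype=float)
        out = np.exp(self.beta1 * x + self.beta2 * x ** 2)
        return out if out.ndim else float(out)


@dataclass
class ConditionalFitResult:
    estimates: list[RateRatioEstimate]
    loglik: float
    converged: bool
    n_iter: int
    n_sets_used: int
    n_sets_dropped: int
    covariance: np.ndarray | None = None
    terms: list[str] = field(default_factory=list)

    def __getitem__(self, term: str) -> RateRatioEstimate:
        for e in self.estimates:
            if e.term == term:
                return e
        raise KeyError(term)

    def to_report(self) -> dict:
        return {
            "converged": self.converged,
            "n_iter": self.n_iter,
            "loglik": self.loglik,
            "n_sets_used": self.n_sets_used,
            "n_sets_dropped": self.n_sets_dropped,
            "terms": [
                {"term": e.term, "beta": e.beta, "se": e.se if e.identifiable else None,
                 "rr": e.rr if e.identifiable else None,
                 "ci_low": e.ci_low, "ci_high": e.ci_high,
                 "identifiable": e.identifiable, "separated": e.separated}
                for e in self.estimates],
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_report(), fh, indent=1)


# ---------------------------------------------------------------------------
# likelihood core

def _group_reduce(x: np.ndarray, starts: np.ndarray) -> np.ndarray:
    return np.add.reduceat(x, starts, axis=0)


def conditional_loglik(beta: np.ndarray, X: np.ndarray, starts: np.ndarray,
                       case_rows: np.ndarray) -> float:
    """Log conditional likelihood (case row first in each group)."""
    eta = X @ beta
    mx = np.maximum.reduceat(eta, starts)
    sizes = np.diff(np.append(starts, len(eta)))
    lse = mx + np.log(_group_reduce(np.exp(eta - np.repeat(mx, sizes)), starts))
    return float(eta[case_rows].sum() - lse.sum())


def _newton_fit(X: np.ndarray, starts: np.ndarray, case_rows: np.ndarray,
                tol: float = 1e-8, max_iter: int = 60):
    n, k = X.shape
    beta = np.zeros(k)
    sizes = np.diff(np.append(starts, n))
    group = np.repeat(np.arange(len(starts)), sizes)
    ll = conditional_loglik(beta, X, starts, case_rows)
    converged = False
    it = 0
    cov = np.full((k, k), np.nan)
    for it in range(1, max_iter + 1):
        eta = X @ beta
        mx = np.maximum.reduceat(eta, starts)
        ex = np.exp(eta - mx[group])
        denom = _group_reduce(ex, starts)
        p = ex / denom[group]
        s1 = _group_reduce(p[:, None] * X, starts)           # per-set mean of x
        grad = X[case_rows].sum(axis=0) - s1.sum(axis=0)
        info = X.T @ (p[:, None] * X) - s1.T @ s1
        if np.max(np.abs(grad)) < tol:
            converged = True
            break
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(info, grad, rcond=None)[0]
        # step-halving to guarantee ascent
        t = 1.0
        for _ in range(40):
            new_ll = conditional_loglik(beta + t * step, X, starts, case_rows)
            if new_ll >= ll - 1e-12:
                break
            t *= 0.5
        beta = beta + t * step
        ll = new_ll
    separated = (not converged) or bool(np.max(np.abs(beta)) > 15)
    if not separated:
        eta = X @ beta
        mx = np.maximum.reduceat(eta, starts)
        ex = np.exp(eta - mx[group])
        denom = _group_reduce(ex, starts)
        p = ex / denom[group]
        s1 = _group_reduce(p[:, None] * X, starts)
        info = X.T @ (p[:, None] * X) - s1.T @ s1
        try:
            cov = np.linalg.inv(info)
        except np.linalg.LinAlgError:
            cov = np.linalg.pinv(info)
    return beta, cov, ll, converged and not separated, separated, it


# ---------------------------------------------------------------------------
# design-matrix assembly

_COVARIATE_CODING = {"race": ("nonwhite", 1), "sex": ("female", 1), "pay_type": ("salary", 1)}


def _assemble(risk_sets: list[RiskSet], exposure: str,
              covariates: tuple[str, ...] = (),
              scores: dict[int, float] | None = None):
    """Stack risk sets into (X, group starts, case rows, term names)."""
    usable = [rs for rs in risk_sets if not rs.excluded and rs.control_ids]
    dropped = len(risk_sets) - len(usable)
    if not usable:
        raise ValueError("no usable (non-empty) risk sets")
    cats = sorted({v[0] for rs in usable for v in rs.exposure_at_event.values()})
    baseline = cats[0] if cats else 0

    if exposure == "categories":
        exp_terms = [f"category_{c}" for c in cats if c != baseline]
    elif exposure == "exposed":
        exp_terms = ["exposed"]
    elif exposure == "score":
        exp_terms = ["trend_score"]
    elif exposure == "cumulative":
        exp_terms = ["cumulative"]
    elif exposure == "linquad":
        exp_terms = ["linear", "quadratic"]
    elif exposure == "aie":
        exp_terms = ["aie"]
    else:
        raise ValueError(f"unknown exposure coding {exposure!r}")
    cov_terms = [f"{c}_{_COVARIATE_CODING[c][0]}" for c in covariates]
    terms = exp_terms + cov_terms

    rows, starts, case_rows = [], [], []
    pos = 0
    for rs in usable:
        starts.append(pos)
        case_rows.append(pos)
        for wid in (rs.case_id, *rs.control_ids):
            cat, cum, aie = rs.exposure_at_event[wid]
            if exposure == "categories":
                x = [1.0 if cat == c else 0.0 for c in cats if c != baseline]
            elif exposure == "exposed":
                x = [1.0 if cat != baseline else 0.0]
            elif exposure == "score":
                x = [float(scores[cat]) if scores else float(cat)]
            elif exposure == "cumulative":
                x = [cum]
            elif exposure == "linquad":
                x = [cum, cum * cum]
            else:
                x = [aie]
            race, sex, pay = rs.covariates[wid]
            vals = {"race": race, "sex": sex, "pay_type": pay}
            for c in covariates:
                level, _ = _COVARIATE_CODING[c]
                x.append(1.0 if vals[c] == level else 0.0)
            rows.append(x)
            pos += 1
    X = np.asarray(rows, dtype=float)
    return X, np.asarray(starts), np.asarray(case_rows), terms, len(usable), dropped, cats


def _within_set_variation(X: np.ndarray, starts: np.ndarray) -> np.ndarray:
    sizes = np.diff(np.append(starts, len(X)))
    group = np.repeat(np.arange(len(starts)), sizes)
    means = _group_reduce(X, starts) / sizes[:, None]
    resid = X - means[group]
    return (resid ** 2).sum(axis=0)


def _fit(X, starts, case_rows, terms, n_used, n_dropped):
    variation = _within_set_variation(X, starts)
    keep = variation > 1e-12
    estimates: list[RateRatioEstimate] = []
    if keep.any():
        beta, cov, ll, converged, separated, it = _newton_fit(X[:, keep], starts, case_rows)
        kk = np.flatnonzero(keep)
        full_beta = np.zeros(len(terms))
        full_var = np.full(len(terms), np.nan)
        full_beta[kk] = beta
        if not separated:
            full_var[kk] = np.diag(cov)
        for j, term in enumerate(terms):
            if not keep[j]:
                estimates.append(RateRatioEstimate(term, 0.0, np.nan, identifiable=False))
            else:
                estimates.append(RateRatioEstimate(
                    term, float(full_beta[j]),
                    float(full_var[j]) if not separated else float("inf"),
                    identifiable=True, separated=separated))
        cov_full = None
        if not separated:
            cov_full = np.full((len(terms), len(terms)), np.nan)
            cov_full[np.ix_(kk, kk)] = cov
        return ConditionalFitResult(estimates, ll, converged, it, n_used, n_dropped,
                                    covariance=cov_full, terms=list(terms))
    # nothing varies within any set
    for term in terms:
        estimates.append(RateRatioEstimate(term, 0.0, np.nan, identifiable=False))
    return ConditionalFitResult(estimates, 0.0, True, 0, n_used, n_dropped,
                                terms=list(terms))


# ---------------------------------------------------------------------------
# public fitting interface

def fit_conditional(risk_sets: list[RiskSet], exposure: str = "categories",
                    covariates: tuple[str, ...] = ("race", "sex", "pay_type"),
                    scores: dict[int, float] | None = None) -> ConditionalFitResult:
    """Maximise the conditional likelihood over the supplied risk sets.

    ``exposure`` selects the exposure coding: ``"categories"`` (indicator
    per non-baseline category), ``"exposed"`` (any non-baseline category),
    ``"score"`` (single ordinal score), ``"cumulative"``, ``"aie"``, or
    ``"linquad"`` (linear + quadratic in cumulative exposure).
    """
    X, starts, case_rows, terms, n_used, n_dropped = _assemble(
        risk_sets, exposure, covariates, scores)[:6]
    return _fit(X, starts, case_rows, terms, n_used, n_dropped)


def fit_log_linear_quadratic(risk_sets: list[RiskSet],
                             covariates: tuple[str, ...] = ("race", "sex", "pay_type"),
                             ) -> DoseResponseModel:
    """Two-parameter log-linear-quadratic dose-response in cumulative exposure.

    Columns are standardised internally for numerical stability and the
    coefficients transformed back to the ppm-years scale.
    """
    X, starts, case_rows, terms, n_used, n_dropped = _assemble(
        risk_sets, "linquad", covariates)[:6]
    scale = X[:, :2].std(axis=0)
    scale[scale == 0] = 1.0
    Xs = X.copy()
    Xs[:, 0] /= scale[0]
    Xs[:, 1] /= scale[1]
    res = _fit(Xs, starts, case_rows, terms, n_used, n_dropped)
    e1, e2 = res.estimates[0], res.estimates[1]
    if not (e1.identifiable and e2.identifiable):
        return DoseResponseModel(0.0, 0.0, np.zeros((2, 2)), identifiable=False)
    cov = np.zeros((2, 2))
    if res.covariance is not None:
        cov = res.covariance[:2, :2] / np.outer(scale[:2], scale[:2])
    return DoseResponseModel(e1.beta / scale[0], e2.beta / scale[1], cov,
                             identifiable=True, separated=e1.separated)


def rr_trend_test(risk_sets: list[RiskSet], scores: dict[int, float] | None = None,
                  covariates: tuple[str, ...] = ("race", "sex", "pay_type")) -> float:
    """Two-sided Wald p for a single ordinal exposure-score term.

    Scores default to category ranks; a mapping from category index to
    score (e.g. category means) may be supplied.
    """
    cats = {v[0] for rs in risk_sets if not rs.excluded
            for v in rs.exposure_at_event.values()}
    if len(cats) < 3:
        raise ValueError("trend test needs at least 3 exposure categories")
    res = fit_conditional(risk_sets, exposure="score", covariates=covariates, scores=scores)
    est = res["trend_score"]
    if not est.identifiable:
        raise ValueError("trend score does not vary within risk sets")
    z = est.beta / est.se
    return float(2 * stats.norm.sf(abs(z)))
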