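"""Progression-free-survival machinery: KM, log-rank, Cox regression.

Event derivation implements the stage-4s observation rule: in trial
INES99.2 patients without upfront treatment, a progression within the
first 2 months of observation is not counted as an event (follow-up
continues).  Kaplan-Meier estimation carries Greenwood standard errors;
group comparison uses the standard log-rank chi-square.  The Cox
proportional-hazards fit maximises the partial likelihood by
Newton-Raphson with Breslow tie handling (Efron optional) and reports
Wald 95% confidence intervals; a backward model-building procedure drops
the least significant covariate until every retained covariate has a Wald
P <= alpha.

The Cox implementation is self-contained so that its score test at beta=0
can be checked against the log-rank statistic (a classical identity) and
its estimates against an independent library fit in the test suite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import TestResult

__all__ = [
    "SurvivalRecord",
    "KMCurve",
    "CoxFit",
    "derive_pfs",
    "km_estimate",
    "logrank_test",
    "cox_fit",
    "backward_select",
]

_Z95 = sps.norm.ppf(0.975)


@dataclass
class SurvivalRecord:
    patient_id: str
    time_months: float
    event: int
    groups: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not np.isfinite(self.time_months) or self.time_months <= 0:
            raise ValueError(f"{self.patient_id}: non-positive follow-up time")
        self.event = int(self.event)


@dataclass
class KMCurve:
    """Product-limit estimate with Greenwood standard errors."""

    times: np.ndarray  # unique event times
    survival: np.ndarray
    std_err: np.ndarray
    at_risk: np.ndarray
    n_events: np.ndarray

    def survival_at(self, t: float) -> float:
        """S(t): step function, right-continuous."""
        k = np.searchsorted(self.times, t, side="right")
        return 1.0 if k == 0 else float(self.survival[k - 1])

    def std_err_at(self, t: float) -> float:
        k = np.searchsorted(self.times, t, side="right")
        return 0.0 if k == 0 else float(self.std_err[k - 1])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.times,
                "survival": self.survival,
                "std_err": self.std_err,
                "at_risk": self.at_risk,
                "n_events": self.n_events,
            }
        )


@dataclass
class CoxFit:
    """Cox proportional-hazards estimates and Wald inference."""

    covariates: list[str]
    coef: np.ndarray
    se: np.ndarray
    log_likelihood: float
    converged: bool
    n: int
    n_events: int
    score_statistic: float  # score test at beta = 0
    ties: str

    @property
    def hazard_ratios(self) -> np.ndarray:
        return np.exp(self.coef)

    @property
    def ci_lower(self) -> np.ndarray:
        return np.exp(self.coef - _Z95 * self.se)

    @property
    def ci_upper(self) -> np.ndarray:
        return np.exp(self.coef + _Z95 * self.se)

    @property
    def p_values(self) -> np.ndarray:
        return sps.chi2.sf((self.coef / self.se) ** 2, df=1)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coef": self.coef,
                "HR": self.hazard_ratios,
                "se(coef)": self.se,
                "ci95_lower": self.ci_lower,
                "ci95_upper": self.ci_upper,
                "p": self.p_values,
            },
            index=self.covariates,
        )


def derive_pfs(clinical) -> SurvivalRecord:
    """Derive the PFS record from one clinical row.

    Expects fields ``patient_id, trial, upfront_chemo, followup_months,
    event`` and, when ``event`` is set, ``progression_months`` (defaults
    to ``followup_months``).  Stage-4s rule: an INES99.2 patient without
    upfront treatment whose progression occurred at <= 2 months has that
    progression ignored; follow-up continues and the record is censored at
    last follow-up unless a later event is recorded.
    """
    followup = float(clinical["followup_months"])
    if not np.isfinite(followup) or followup <= 0:
        raise ValueError(f"{clinical['patient_id']}: non-positive follow-up")
    event = int(clinical["event"])
    time = followup
    if event:
        prog = clinical.get("progression_months")
        prog = followup if prog is None or (isinstance(prog, float) and np.isnan(prog)) else float(prog)
        untreated_4s = clinical["trial"] == "INES99.2" and not bool(clinical["upfront_chemo"])
        if untreated_4s and prog <= 2.0:
            event, time = 0, followup
        else:
            time = prog
    groups = {
        k: clinical[k]
        for k in ("genomic_type", "trial", "symptoms_at_diagnosis", "upfront_chemo")
        if k in clinical
    }
    return SurvivalRecord(
        patient_id=str(clinical["patient_id"]), time_months=time, event=event, groups=groups
    )


def _times_events(records) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray([r.time_months for r in records], dtype=float)
    e = np.asarray([r.event for r in records], dtype=int)
    return t, e


def km_estimate(records) -> KMCurve:
    """Kaplan-Meier product-limit estimate with Greenwood variance."""
    records = list(records)
    if not records:
        raise ValueError("no records")
    t, e = _times_events(records)
    event_times = np.unique(t[e == 1])
    surv, se, at_risk, n_ev = [], [], [], []
    s = 1.0
    gw = 0.0  # running Greenwood sum d / (n (n - d))
    for u in event_times:
        n = int((t >= u).sum())
        d = int(((t == u) & (e == 1)).sum())
        s *= 1.0 - d / n
        if n > d:
            gw += d / (n * (n - d))
            se.append(s * np.sqrt(gw))
        else:
            se.append(0.0)  # S hits 0; variance degenerate
        surv.append(s)
        at_risk.append(n)
        n_ev.append(d)
    return KMCurve(
        times=event_times,
        survival=np.asarray(surv),
        std_err=np.asarray(se),
        at_risk=np.asarray(at_risk, dtype=int),
        n_events=np.asarray(n_ev, dtype=int),
    )


def logrank_test(records, group_key: str) -> TestResult:
    """Log-rank chi-square across the groups defined by ``group_key``."""
    records = list(records)
    labels = sorted({r.groups[group_key] for r in records}, key=str)
    if len(labels) < 2:
        raise ValueError("log-rank test needs at least 2 groups")
    t, e = _times_events(records)
    g = np.asarray([labels.index(r.groups[group_key]) for r in records])
    if e.sum() == 0:
        raise ValueError("log-rank test needs at least one event")

    k = len(labels)
    observed = np.zeros(k)
    expected = np.zeros(k)
    var = np.zeros((k - 1, k - 1))
    for u in np.unique(t[e == 1]):
        risk = t >= u
        n = int(risk.sum())
        d = int((e[t == u] == 1).sum())
        ng = np.bincount(g[risk], minlength=k).astype(float)
        dg = np.bincount(g[(t == u) & (e == 1)], minlength=k).astype(float)
        observed += dg
        expected += d * ng / n
        if n > 1:
            p = ng / n
            # hypergeometric covariance of the event-count vector
            cov = d * (np.diag(p) - np.outer(p, p)) * (n - d) / (n - 1)
            var += cov[: k - 1, : k - 1]
    diff = (observed - expected)[: k - 1]
    stat = float(diff @ np.linalg.pinv(var) @ diff)
    p_value = float(sps.chi2.sf(stat, df=k - 1))
    return TestResult(statistic=stat, df=k - 1, p_value=p_value, method="LOG_RANK")


def _cox_derivatives(beta, t, e, X, ties):
    """Log partial likelihood, score vector and information matrix."""
    eta = X @ beta
    w = np.exp(eta)
    loglik = 0.0
    p = X.shape[1]
    U = np.zeros(p)
    I = np.zeros((p, p))
    for u in np.unique(t[e == 1]):
        risk = t >= u
        d_idx = (t == u) & (e == 1)
        d = int(d_idx.sum())
        xr = X[risk]
        wr = w[risk]
        s0 = wr.sum()
        s1 = xr.T @ wr
        s2 = (xr * wr[:, None]).T @ xr
        xd = X[d_idx]
        if ties == "breslow" or d == 1:
            loglik += eta[d_idx].sum() - d * np.log(s0)
            U += xd.sum(axis=0) - d * s1 / s0
            I += d * (s2 / s0 - np.outer(s1 / s0, s1 / s0))
        else:  # efron
            wd = w[d_idx]
            s0d = wd.sum()
            s1d = xd.T @ wd
            s2d = (xd * wd[:, None]).T @ xd
            loglik += eta[d_idx].sum()
            for m in range(d):
                f = m / d
                denom = s0 - f * s0d
                num1 = s1 - f * s1d
                num2 = s2 - f * s2d
                loglik -= np.log(denom)
                U -= num1 / denom
                I += num2 / denom - np.outer(num1 / denom, num1 / denom)
            U += xd.sum(axis=0)
    return loglik, U, I


def cox_fit(
    records,
    covariates: list[str],
    ties: str = "breslow",
    tol: float = 1e-8,
    max_iter: int = 50,
) -> CoxFit:
    """Fit a Cox proportional-hazards model by Newton-Raphson.

    ``records`` may be SurvivalRecords (covariates read from ``groups``)
    or a DataFrame with ``time_months``/``event`` columns.  Raises on a
    rank-deficient covariate matrix (e.g. a constant covariate); flags,
    rather than hides, non-convergence.
    """
    if ties not in ("breslow", "efron"):
        raise ValueError(f"unknown tie handling {ties!r}")
    if isinstance(records, pd.DataFrame):
        df = records
        t = df["time_months"].to_numpy(dtype=float)
        e = df["event"].to_numpy(dtype=int)
        X = df[list(covariates)].to_numpy(dtype=float)
    else:
        records = list(records)
        t, e = _times_events(records)
        X = np.asarray([[float(r.groups[c]) for c in covariates] for r in records])
    if e.sum() == 0:
        raise ValueError("no events")
    if np.linalg.matrix_rank(X - X.mean(axis=0)) < X.shape[1]:
        raise ValueError("covariate matrix is rank deficient (constant or collinear column)")

    beta = np.zeros(X.shape[1])
    loglik, U, I = _cox_derivatives(beta, t, e, X, ties)
    score_stat = float(U @ np.linalg.pinv(I) @ U)
    converged = False
    for _ in range(max_iter):
        step = np.linalg.pinv(I) @ U
        # step-halving keeps the partial likelihood non-decreasing
        factor = 1.0
        for _half in range(30):
            new_beta = beta + factor * step
            new_loglik, new_U, new_I = _cox_derivatives(new_beta, t, e, X, ties)
            if new_loglik >= loglik - 1e-12:
                break
            factor /= 2.0
        delta = np.max(np.abs(new_beta - beta))
        beta, loglik, U, I = new_beta, new_loglik, new_U, new_I
        if np.max(np.abs(beta)) > 30:  # monotone likelihood / separation
            warnings.warn("possible separation: coefficient diverging", stacklevel=2)
            break
        if delta < tol:
            converged = True
            break
    with np.errstate(invalid="ignore"):
        se = np.sqrt(np.clip(np.diag(np.linalg.pinv(I)), 0.0, None))
    return CoxFit(
        covariates=list(covariates),
        coef=beta,
        se=se,
        log_likelihood=float(loglik),
        converged=converged,
        n=len(t),
        n_events=int(e.sum()),
        score_statistic=score_stat,
        ties=ties,
    )


def backward_select(
    records,
    candidates: list[str],
    alpha: float = 0.05,
    ties: str = "breslow",
) -> tuple[CoxFit | None, list[str]]:
    """Backward elimination: drop the covariate with the largest Wald
    P > alpha, refit, and stop when all retained have P <= alpha.

    Returns ``(fit, retained)``; ``(None, [])`` if every candidate is
    eliminated.
    """
    retained = list(candidates)
    fit = None
    while retained:
        fit = cox_fit(records, retained, ties=ties)
        p = fit.p_values
        worst = int(np.argmax(p))
        if p[worst] <= alpha:
            return fit, retained
        retained.pop(worst)
    return None, []
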