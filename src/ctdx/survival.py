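"""Survival machinery: benefit labeling, Kaplan-Meier, log-rank, Cox
proportional hazards, and the maximally selected rank-statistic cutpoint.

Kaplan-Meier curves are backed by lifelines.  The log-rank statistic is
computed in-package from the risk table because the cutpoint scan evaluates
it once per candidate split, and the Cox model is fitted in-package by
Newton maximization of the partial likelihood (Efron or Breslow ties,
gradient max-norm < 1e-8) so that fitted optima can be audited directly;
lifelines serves as the independent cross-check for both in the test suite.
The partial log-likelihood itself is exposed for finite-difference gradient
checks and the score test at β = 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from lifelines import KaplanMeierFitter

from .errors import ValidationError

__all__ = [
    "KMCurve",
    "LogRankResult",
    "CoxResult",
    "CutpointResult",
    "dcb_label",
    "km_fit",
    "km_median",
    "logrank_test",
    "two_group_logrank_z",
    "cox_fit",
    "cox_partial_loglik",
    "cox_score_test",
    "optimal_cutpoint",
    "INDETERMINATE",
]

DCB = "DCB"
NDB = "NDB"
INDETERMINATE = "indeterminate"


def _as_arrays(time, event) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=bool)
    if t.size == 0:
        raise ValidationError("empty survival data")
    if t.shape != e.shape:
        raise ValidationError("time and event must have the same length")
    if (t <= 0).any():
        raise ValidationError("survival times must be > 0")
    return t, e


def dcb_label(time_months: float, event: bool, window: float = 6.0) -> str:
    """Durable-clinical-benefit label from one PFS record.

    Progression-free for at least ``window`` months (inclusive) is DCB;
    progression or death before the window is NDB; censoring before the
    window leaves the benefit status unknowable (``indeterminate``), matching
    the exclusion of patients with insufficient follow-up.
    """
    if time_months <= 0:
        raise ValidationError(f"PFS time must be > 0, got {time_months}")
    if time_months >= window:
        return DCB
    return NDB if event else INDETERMINATE


@dataclass
class KMCurve:
    """Product-limit estimate: step function S(t) with at-risk counts."""

    times: np.ndarray            # ordered distinct observed times (events first at ties)
    survival: np.ndarray         # S(t) just after each time
    at_risk: np.ndarray
    n_events: np.ndarray
    median: float | None         # earliest time with S <= 0.5; None if never reached


def km_fit(time, event) -> KMCurve:
    """Kaplan-Meier product-limit fit of one survival sample."""
    t, e = _as_arrays(time, event)
    kmf = KaplanMeierFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        kmf.fit(t, e)
    times = kmf.survival_function_.index.to_numpy(dtype=float)
    surv = kmf.survival_function_["KM_estimate"].to_numpy(dtype=float)
    keep = times > 0
    times, surv = times[keep], surv[keep]
    table = kmf.event_table.reindex(times)
    med = km_median_from_curve(times, surv)
    return KMCurve(
        times=times,
        survival=surv,
        at_risk=table["at_risk"].to_numpy(dtype=float),
        n_events=table["observed"].to_numpy(dtype=float),
        median=med,
    )


def km_median_from_curve(times: np.ndarray, survival: np.ndarray) -> float | None:
    idx = np.nonzero(survival <= 0.5)[0]
    return float(times[idx[0]]) if idx.size else None


def km_median(curve: KMCurve) -> float | None:
    """Earliest time at which the survival estimate drops to 0.5 or below."""
    return curve.median


@dataclass
class LogRankResult:
    chi_square: float
    degrees_of_freedom: int
    p_value: float


def _risk_table(t: np.ndarray, e: np.ndarray, g: np.ndarray, k: int):
    """Per distinct event time: at-risk and observed events, total and per group."""
    order = np.argsort(t)
    t, e, g = t[order], e[order], g[order]
    ev_times = np.unique(t[e])
    # counts per group at risk just before each event time, via cumulative counts
    n = t.size
    d = np.zeros((ev_times.size, k))
    r = np.zeros((ev_times.size, k))
    for j in range(k):
        tj = t[g == j]
        ej = e[g == j]
        r[:, j] = tj.size - np.searchsorted(np.sort(tj), ev_times, side="left")
        te = np.sort(tj[ej])
        d[:, j] = np.searchsorted(te, ev_times, side="right") - np.searchsorted(te, ev_times, side="left")
    return ev_times, r, d


def logrank_test(time, event, groups) -> LogRankResult:
    """k-sample log-rank test (observed minus expected, hypergeometric
    variance), df = k − 1."""
    t, e = _as_arrays(time, event)
    glab, g = np.unique(np.asarray(groups), return_inverse=True)
    k = glab.size
    if k < 2:
        raise ValidationError("logrank_test needs at least 2 groups")
    for j in range(k):
        if not np.any(g == j):  # pragma: no cover - unique() precludes this
            raise ValidationError(f"group {glab[j]!r} is empty")
    _, r, d = _risk_table(t, e, g, k)
    R = r.sum(axis=1)
    D = d.sum(axis=1)
    exp = r * (D / R)[:, None]
    O_minus_E = (d - exp).sum(axis=0)
    # hypergeometric covariance, summed over event times
    V = np.zeros((k, k))
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.where(R > 1, D * (R - D) / (R - 1), 0.0)
    for a in range(k):
        for b in range(k):
            pa = r[:, a] / R
            pb = r[:, b] / R
            V[a, b] = np.sum(f * pa * ((a == b) - pb))
    v = O_minus_E[:-1]
    Vm = V[:-1, :-1]
    chi2 = float(v @ np.linalg.pinv(Vm) @ v) if v.size else 0.0
    chi2 = max(chi2, 0.0)
    p = float(stats.chi2.sf(chi2, k - 1))
    return LogRankResult(chi_square=chi2, degrees_of_freedom=k - 1, p_value=min(max(p, np.nextafter(0, 1)), 1.0))


def two_group_logrank_z(time, event, in_high) -> float:
    """Standardized two-group log-rank statistic U/√V (sign: positive when
    the high group has more events than expected)."""
    t, e = _as_arrays(time, event)
    g = np.asarray(in_high, dtype=bool).astype(int)
    if g.min() == g.max():
        raise ValidationError("both groups must be nonempty")
    _, r, d = _risk_table(t, e, g, 2)
    R = r.sum(axis=1)
    D = d.sum(axis=1)
    U = float(np.sum(d[:, 1] - r[:, 1] * D / R))
    with np.errstate(invalid="ignore", divide="ignore"):
        V = np.where(
            R > 1, D * (r[:, 0] * r[:, 1]) * (R - D) / (R**2 * (R - 1)), 0.0
        ).sum()
    if V <= 0:
        return 0.0
    return U / float(np.sqrt(V))


@dataclass
class CoxResult:
    """Cox proportional-hazards fit summary."""

    names: list[str]
    coef: np.ndarray
    hr: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    p: np.ndarray
    log_likelihood: float
    converged: bool

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({
            "coef": self.coef, "HR": self.hr,
            "HR 95% lower": self.ci_lower, "HR 95% upper": self.ci_upper,
            "p": self.p,
        }, index=self.names)


def _cox_quantities(beta, t, e, X, tie_method: str):
    """Partial log-likelihood, gradient and Hessian at ``beta``."""
    n, p = X.shape
    eta = X @ beta
    w = np.exp(eta)
    ll = 0.0
    grad = np.zeros(p)
    hess = np.zeros((p, p))
    for td in np.unique(t[e]):
        at_risk = t >= td
        D = e & (t == td)
        m = int(D.sum())
        Xr = X[at_risk]
        wr = w[at_risk]
        S0 = float(wr.sum())
        S1 = wr @ Xr
        S2 = (Xr * wr[:, None]).T @ Xr
        ll += float(eta[D].sum())
        grad += X[D].sum(axis=0)
        if tie_method == "breslow" or m == 1:
            ll -= m * np.log(S0)
            grad -= m * S1 / S0
            hess -= m * (S2 / S0 - np.outer(S1, S1) / S0**2)
        elif tie_method == "efron":
            wd = w[D]
            Xd = X[D]
            S0d = float(wd.sum())
            S1d = wd @ Xd
            S2d = (Xd * wd[:, None]).T @ Xd
            for l in range(m):
                f = l / m
                s0 = S0 - f * S0d
                s1 = S1 - f * S1d
                s2 = S2 - f * S2d
                ll -= np.log(s0)
                grad -= s1 / s0
                hess -= s2 / s0 - np.outer(s1, s1) / s0**2
        else:
            raise ValidationError(f"unknown tie_method {tie_method!r}")
    return ll, grad, hess


def cox_fit(time, event, covariates, tie_method: str = "efron",
            tol: float = 1e-8, max_iter: int = 100) -> CoxResult:
    """Cox proportional-hazards regression (uni- or multivariate).

    Newton maximization of the partial likelihood with step halving (the
    log partial likelihood never decreases across iterations); Efron tie
    handling by default, Breslow available.  Convergence at gradient
    max-norm below ``tol``.  A monotone likelihood (separation) leaves the
    result flagged unconverged with a warning.
    """
    t, e = _as_arrays(time, event)
    if e.sum() < 1:
        raise ValidationError("cox_fit needs at least one event")
    Xdf = pd.DataFrame(covariates)
    Xdf.columns = [str(c) for c in Xdf.columns]
    names = list(Xdf.columns)
    X = Xdf.to_numpy(dtype=float)
    for j, c in enumerate(names):
        if np.ptp(X[:, j]) == 0:
            raise ValidationError(f"covariate {c!r} is constant")
    p = X.shape[1]

    beta = np.zeros(p)
    ll, grad, hess = _cox_quantities(beta, t, e, X, tie_method)
    converged = False
    for _ in range(max_iter):
        if np.max(np.abs(grad)) < tol:
            converged = True
            break
        try:
            step = np.linalg.solve(-hess, grad)
        except np.linalg.LinAlgError:  # pragma: no cover - near-singular information
            step = np.linalg.lstsq(-hess, grad, rcond=None)[0]
        # accept any step that does not lower the likelihood beyond float noise
        noise = 1e-12 * max(1.0, abs(ll))
        alpha = 1.0
        for _ in range(30):
            cand = beta + alpha * step
            cll, cgrad, chess = _cox_quantities(cand, t, e, X, tie_method)
            if np.isfinite(cll) and cll >= ll - noise:
                break
            alpha *= 0.5
        beta, ll, grad, hess = cand, cll, cgrad, chess
    else:
        converged = bool(np.max(np.abs(grad)) < tol)
    if not converged:
        warnings.warn(
            "Cox fit did not converge (possible monotone likelihood / separation)",
            RuntimeWarning,
        )

    cov = np.linalg.pinv(-hess)
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    z975 = stats.norm.ppf(0.975)
    with np.errstate(divide="ignore", invalid="ignore"):
        zstat = np.where(se > 0, beta / se, np.inf)
    ll_final = cox_partial_loglik(beta, t, e, X, tie_method)
    return CoxResult(
        names=names,
        coef=beta,
        hr=np.exp(beta),
        ci_lower=np.exp(beta - z975 * se),
        ci_upper=np.exp(beta + z975 * se),
        p=2 * stats.norm.sf(np.abs(zstat)),
        log_likelihood=ll_final,
        converged=converged,
    )


def cox_partial_loglik(beta, time, event, covariates, tie_method: str = "efron") -> float:
    """Cox partial log-likelihood at ``beta`` with Breslow or Efron ties.

    Exposed so fitted optima can be audited (finite-difference gradients,
    score tests) independently of any fitting backend.
    """
    t, e = _as_arrays(time, event)
    X = np.asarray(pd.DataFrame(covariates), dtype=float)
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    eta = X @ beta
    w = np.exp(eta)
    ll = 0.0
    for td in np.unique(t[e]):
        at_risk = t >= td
        D = e & (t == td)
        m = int(D.sum())
        ll += float(eta[D].sum())
        S = float(w[at_risk].sum())
        if tie_method == "breslow" or m == 1:
            ll -= m * np.log(S)
        elif tie_method == "efron":
            Sd = float(w[D].sum())
            for l in range(m):
                ll -= np.log(S - (l / m) * Sd)
        else:
            raise ValidationError(f"unknown tie_method {tie_method!r}")
    return ll


def cox_score_test(time, event, covariates, tie_method: str = "efron") -> float:
    """Score (Rao) chi-square for H0: β = 0, U(0)ᵀ I(0)⁻¹ U(0) from the
    partial-likelihood gradient and information."""
    t, e = _as_arrays(time, event)
    X = np.asarray(pd.DataFrame(covariates), dtype=float)
    _, grad, hess = _cox_quantities(np.zeros(X.shape[1]), t, e, X, tie_method)
    return float(grad @ np.linalg.solve(-hess, grad))


@dataclass
class CutpointResult:
    """Outcome of the maximally selected rank-statistic scan."""

    cutpoint: float
    statistic: float             # max |standardized log-rank| over admissible splits
    n_low: int
    n_high: int
    scan: pd.DataFrame = field(repr=False)   # all admissible candidates


def optimal_cutpoint(values, time, event, minprop: float = 0.1) -> CutpointResult:
    """Maximally selected log-rank cutpoint for a continuous covariate.

    Candidates are the distinct observed values; a split assigns
    ``value <= c`` to the low group.  Splits leaving either side below
    ``minprop`` of the subjects are inadmissible.  Returns the candidate with
    the largest absolute standardized two-group log-rank statistic (ties go
    to the smallest cutpoint) together with the full scan table.
    """
    x = np.asarray(values, dtype=float)
    t, e = _as_arrays(time, event)
    if x.shape != t.shape:
        raise ValidationError("values and survival records must align")
    uniq = np.unique(x)
    if uniq.size < 2:
        raise ValidationError("need at least 2 distinct covariate values")
    n = x.size
    min_n = minprop * n
    rows = []
    for c in uniq[:-1]:
        low = x <= c
        n_low = int(low.sum())
        n_high = n - n_low
        if n_low < min_n or n_high < min_n:
            continue
        z = two_group_logrank_z(t, e, ~low)
        rows.append((float(c), z, n_low, n_high))
    if not rows:
        raise ValidationError(
            f"no admissible cutpoint: every split leaves a group below minprop={minprop}"
        )
    scan = pd.DataFrame(rows, columns=["cutpoint", "z", "n_low", "n_high"])
    best = scan.loc[scan["z"].abs().idxmax()]
    return CutpointResult(
        cutpoint=float(best["cutpoint"]),
        statistic=float(abs(best["z"])),
        n_low=int(best["n_low"]),
        n_high=int(best["n_high"]),
        scan=scan,
    )
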