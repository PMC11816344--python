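"""Survival-analysis primitives: Kaplan–Meier, log-rank, Cox PH, time-dependent ROC.

These are the building blocks of the biomarker screen.  The Cox fitter is a
compact Newton–Raphson maximizer of the Efron-corrected partial likelihood;
it is deliberately lightweight because the screen calls it tens of thousands
of times (once or more per gene per cohort).  Kaplan–Meier and log-rank wrap
``lifelines``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test, multivariate_logrank_test
from scipy import stats

__all__ = [
    "KMCurve",
    "LogRankResult",
    "CoxFit",
    "SurvivalROC",
    "km_fit",
    "log_rank",
    "cox_fit",
    "survival_auc",
]

#: hard cap on |log HR|; a coefficient walking past this during Newton
#: iterations signals a monotone partial likelihood (complete separation).
_COEF_CAP = 15.0


def _check_surv_arrays(times, events) -> tuple[np.ndarray, np.ndarray]:
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=float)
    if times.size == 0:
        raise ValueError("empty survival data")
    if times.shape != events.shape:
        raise ValueError("times and events must have the same length")
    if np.any(times < 0):
        raise ValueError("negative survival times")
    if not np.all(np.isin(events, (0.0, 1.0))):
        raise ValueError("events must be binary 0/1")
    return times, events.astype(int)


@dataclass
class KMCurve:
    """Product-limit survival curve with a step-function accessor."""

    event_times: np.ndarray  # increasing, distinct observed times
    survival: np.ndarray     # S(t) right after each time; non-increasing
    at_risk: np.ndarray      # number at risk just before each time

    def survival_at(self, t, left: bool = False):
        """S(t) (right-continuous); ``left=True`` gives the left limit S(t-)."""
        side = "left" if left else "right"
        idx = np.searchsorted(self.event_times, t, side=side)
        s = np.concatenate([[1.0], self.survival])
        return s[idx]


@dataclass
class LogRankResult:
    chi2: float
    p: float
    groups: tuple


@dataclass
class CoxFit:
    """Cox proportional-hazards fit (Efron ties, Wald inference)."""

    names: list[str]
    coef: np.ndarray
    se: np.ndarray
    p: np.ndarray
    n: int
    n_events: int
    converged: bool
    loglik: float = field(default=np.nan)

    @property
    def hr(self) -> np.ndarray:
        return np.exp(self.coef)

    def summary_row(self, name: str) -> dict:
        i = self.names.index(name)
        return {
            "coef": self.coef[i],
            "hr": float(np.exp(self.coef[i])),
            "se": self.se[i],
            "p": self.p[i],
        }


def km_fit(times, events) -> KMCurve:
    """Kaplan–Meier product-limit estimate with right censoring."""
    times, events = _check_surv_arrays(times, events)
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    tab = kmf.event_table
    # keep only times where the curve is defined (all observed times)
    t = tab.index.to_numpy(dtype=float)
    surv = kmf.survival_function_at_times(t).to_numpy()
    at_risk = tab["at_risk"].to_numpy(dtype=float)
    keep = t > 0 if t[0] == 0 and tab["observed"].iloc[0] == 0 and tab["censored"].iloc[0] == 0 else np.ones(t.size, bool)
    return KMCurve(event_times=t[keep], survival=surv[keep], at_risk=at_risk[keep])


def log_rank(times, events, group_labels) -> LogRankResult:
    """Two-group 1-df log-rank test."""
    times, events = _check_surv_arrays(times, events)
    groups = np.asarray(group_labels)
    labels = np.unique(groups)
    if labels.size != 2:
        raise ValueError(f"log_rank requires exactly 2 groups, got {labels.size}")
    m = groups == labels[0]
    res = logrank_test(times[m], times[~m], events[m], events[~m])
    return LogRankResult(chi2=float(res.test_statistic), p=float(res.p_value), groups=tuple(labels))


def log_rank_multigroup(times, events, group_labels) -> LogRankResult:
    """k-group log-rank test (k-1 df)."""
    times, events = _check_surv_arrays(times, events)
    groups = np.asarray(group_labels)
    res = multivariate_logrank_test(times, groups, events)
    return LogRankResult(chi2=float(res.test_statistic), p=float(res.p_value), groups=tuple(np.unique(groups)))


def _loglik_distinct(beta, X, ev_rows):
    """Partial log-likelihood and derivatives when all times are distinct.

    With no ties Efron and Breslow coincide and every risk set is a prefix
    of the descending-time ordering, so everything is cumulative sums.
    """
    eta = np.clip(X @ beta, -200, 200)
    w = np.exp(eta)
    wX = X * w[:, None]
    S0 = np.cumsum(w)[ev_rows]
    S1 = np.cumsum(wX, axis=0)[ev_rows]
    u = S1 / S0[:, None]
    ll = float(eta[ev_rows].sum() - np.log(S0).sum())
    grad = X[ev_rows].sum(axis=0) - u.sum(axis=0)
    cs_wXX = np.cumsum(np.einsum("ij,ik->ijk", X, wX), axis=0)[ev_rows]
    A = (cs_wXX / S0[:, None, None]).sum(axis=0)
    hess = -(A - u.T @ u)
    return ll, grad, hess


def _efron_loglik_grad_hess(beta, X, times, events):
    """Efron-corrected partial log-likelihood and derivatives.

    Arrays must be sorted by descending time so that the risk set at each
    event time is a prefix (cumulative sums).
    """
    n, p = X.shape
    eta = X @ beta
    eta = np.clip(eta, -200, 200)
    w = np.exp(eta)
    wX = X * w[:, None]
    wXX = np.einsum("ij,ik->ijk", X, wX)

    cs_w = np.cumsum(w)
    cs_wX = np.cumsum(wX, axis=0)
    cs_wXX = np.cumsum(wXX, axis=0)

    ll = 0.0
    grad = np.zeros(p)
    hess = np.zeros((p, p))

    i = 0
    while i < n:
        j = i
        while j < n and times[j] == times[i]:
            j += 1
        # tied block [i, j); events within it
        ev = np.nonzero(events[i:j])[0] + i
        d = ev.size
        if d > 0:
            S0 = cs_w[j - 1]
            S1 = cs_wX[j - 1]
            S2 = cs_wXX[j - 1]
            tw = w[ev].sum()
            tw1 = wX[ev].sum(axis=0)
            tw2 = wXX[ev].sum(axis=0)
            ll += eta[ev].sum()
            grad += X[ev].sum(axis=0)
            for l in range(d):
                f = l / d
                s0 = S0 - f * tw
                s1 = S1 - f * tw1
                s2 = S2 - f * tw2
                ll -= np.log(s0)
                grad -= s1 / s0
                hess -= s2 / s0 - np.outer(s1, s1) / s0**2
        i = j
    return ll, grad, hess


def cox_fit(times, events, covariates, names=None, max_iter: int = 50, tol: float = 1e-9) -> CoxFit:
    """Cox proportional-hazards regression (Efron tie handling, Wald p-values).

    Parameters
    ----------
    covariates
        (n, p) matrix or length-n vector.  Constant columns are rejected.
    names
        Optional covariate names (defaults to ``x0..x{p-1}``).

    A monotone partial likelihood (e.g. one group with zero events) is
    reported with ``converged=False`` and the coefficient clamped at a
    bounded value, never as a silently huge number.
    """
    times, events = _check_surv_arrays(times, events)
    X = np.asarray(covariates, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[0] != times.size:
        raise ValueError("covariate rows must match number of samples")
    n, p = X.shape
    if names is None:
        names = [f"x{i}" for i in range(p)]
    if events.sum() < 1:
        raise ValueError("need at least one event")
    const = np.ptp(X, axis=0) == 0
    if np.any(const):
        raise ValueError(f"constant covariate: {names[int(np.nonzero(const)[0][0])]}")

    # center columns for numerical stability (does not change coef)
    mu = X.mean(axis=0)
    Xc = X - mu
    # descending time; censored sorted before events at equal times so that
    # prefix risk sets keep censored-at-event-time samples at risk
    order = np.lexsort((events, -times))
    Xs, ts, es = Xc[order], times[order], events[order]
    ev_times = ts[es == 1]
    if np.unique(ev_times).size == ev_times.size:
        # no tied events: Efron == Breslow, risk sets are prefixes
        ev_rows = np.nonzero(es)[0]
        objective = lambda b: _loglik_distinct(b, Xs, ev_rows)
    else:
        objective = lambda b: _efron_loglik_grad_hess(b, Xs, ts, es)

    beta = np.zeros(p)
    converged = False
    ll = -np.inf
    for _ in range(max_iter):
        ll, grad, hess = objective(beta)
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            break
        beta_new = beta - step
        if np.any(np.abs(beta_new) > _COEF_CAP):
            beta = np.clip(beta_new, -_COEF_CAP, _COEF_CAP)
            break
        if np.max(np.abs(beta_new - beta)) < tol:
            beta = beta_new
            converged = True
            break
        beta = beta_new

    ll, grad, hess = objective(beta)
    try:
        cov = np.linalg.inv(-hess)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        se = np.full(p, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = beta / se
    pvals = 2 * stats.norm.sf(np.abs(z))
    return CoxFit(names=list(names), coef=beta, se=se, p=pvals,
                  n=n, n_events=int(es.sum()), converged=converged, loglik=ll)


@dataclass
class SurvivalROC:
    """Cumulative-case / dynamic-control ROC at a fixed horizon.

    Cases are samples with an observed event by the horizon, controls are
    samples still at risk past it; inverse-probability-of-censoring weights
    from the Kaplan–Meier estimate of the censoring distribution make the
    estimator consistent under independent right censoring.
    """

    horizon: float
    auc: float
    _case_marker: np.ndarray
    _case_w: np.ndarray
    _ctrl_marker: np.ndarray
    _ctrl_w: np.ndarray

    def sens_at(self, c: float) -> float:
        """Weighted P(marker > c | event by horizon)."""
        return float(self._case_w[self._case_marker > c].sum() / self._case_w.sum())

    def spec_at(self, c: float) -> float:
        """Weighted P(marker <= c | event-free past horizon)."""
        return float(self._ctrl_w[self._ctrl_marker <= c].sum() / self._ctrl_w.sum())


def survival_auc(times, events, marker, horizon: float) -> SurvivalROC:
    """Time-dependent ROC/AUC at ``horizon`` (cumulative/dynamic, KM weights)."""
    times, events = _check_surv_arrays(times, events)
    marker = np.asarray(marker, dtype=float)
    if marker.shape != times.shape:
        raise ValueError("marker must match number of samples")
    if horizon > times.max():
        raise ValueError("horizon exceeds maximum follow-up")

    case = (times <= horizon) & (events == 1)
    ctrl = times > horizon
    if case.sum() == 0:
        raise ValueError("no events before horizon")
    if ctrl.sum() == 0:
        raise ValueError("no samples at risk past horizon")

    # KM of the censoring distribution
    cens_km = km_fit(times, 1 - events)
    g_case = cens_km.survival_at(times[case], left=True)
    g_ctrl = float(cens_km.survival_at(horizon))
    ok = g_case > 0
    w_case = np.where(ok, 1.0 / np.where(ok, g_case, 1.0), 0.0)
    w_ctrl = np.full(int(ctrl.sum()), 1.0 / g_ctrl if g_ctrl > 0 else 0.0)

    mc, mk = marker[case], marker[ctrl]
    # weighted Mann-Whitney AUC with tie credit 1/2
    diff = mc[:, None] - mk[None, :]
    conc = (diff > 0) + 0.5 * (diff == 0)
    W = np.outer(w_case, w_ctrl)
    denom = W.sum()
    auc = float((conc * W).sum() / denom) if denom > 0 else np.nan
    return SurvivalROC(horizon=float(horizon), auc=auc,
                       _case_marker=mc, _case_w=w_case,
                       _ctrl_marker=mk, _ctrl_w=w_ctrl)
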