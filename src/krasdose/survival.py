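"""Survival and categorical statistics built from first principles.

The estimators that carry the scientific weight of the pipeline — the
Kaplan–Meier product-limit curve, the k-group log-rank test, and Cox
proportional-hazards regression with Efron tie handling — are implemented
directly here so that every downstream number (medians, 1/3/5-year rates,
hazard ratios, cutpoint statistics) is fully auditable.  scipy supplies
only reference distributions (chi-square, normal) and the two generic
group-comparison tests (Welch t, rank-sum).

Conventions
-----------
* Time is in months, non-negative floats; ``event`` is 1 for an observed
  event and 0 for right-censoring.
* At a tied time, censored subjects are considered at risk for the event
  occurring at that time (censoring processed after the event).
* All p-values are two-sided.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from scipy import stats as _st

__all__ = [
    "KMCurve",
    "LogRankResult",
    "CoxResult",
    "RecurrenceTimingRule",
    "km_fit",
    "km_median",
    "km_rate_at",
    "logrank_test",
    "cox_fit",
    "cox_score_test",
    "classify_recurrence_timing",
    "chi_square_test",
    "compare_continuous",
]


# ---------------------------------------------------------------------------
# Kaplan–Meier
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class KMCurve:
    """Product-limit estimate of a survival function.

    ``event_times`` are the distinct times with at least one event,
    ascending; ``survival[i]`` is S(t) just after ``event_times[i]``;
    ``at_risk[i]`` and ``n_events[i]`` are the risk-set size and event
    count at that time.  S(0) = 1 by construction.
    """

    event_times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    n_events: np.ndarray
    n_subjects: int

    def __post_init__(self) -> None:
        if np.any(np.diff(self.survival) > 1e-12):
            raise ValueError("survival must be non-increasing")


def _check_times_events(times, events):
    t = np.asarray(times, dtype=float)
    d = np.asarray(events)
    if t.ndim != 1 or d.shape != t.shape:
        raise ValueError("times and events must be 1-d and equal length")
    if t.size == 0:
        raise ValueError("need at least one subject")
    if not np.all(np.isfinite(t)) or np.any(t < 0):
        raise ValueError("times must be finite and non-negative")
    d = d.astype(int)
    if not np.all((d == 0) | (d == 1)):
        raise ValueError("events must be 0/1")
    return t, d


def km_fit(times: Sequence[float], events: Sequence[int]) -> KMCurve:
    """Fit the Kaplan–Meier product-limit estimator."""
    t, d = _check_times_events(times, events)
    order = np.argsort(t, kind="stable")
    t, d = t[order], d[order]
    n = t.size

    # distinct event times; at-risk = subjects with time >= u (censored at u
    # still at risk for the event at u)
    ev_times = np.unique(t[d == 1])
    at_risk = np.empty(ev_times.size, dtype=int)
    n_events = np.empty(ev_times.size, dtype=int)
    for i, u in enumerate(ev_times):
        at_risk[i] = int(np.sum(t >= u))
        n_events[i] = int(np.sum((t == u) & (d == 1)))
    surv = np.cumprod(1.0 - n_events / at_risk)
    return KMCurve(ev_times, surv, at_risk, n_events, n_subjects=n)


def km_median(curve: KMCurve) -> float | None:
    """Smallest time with S(t) <= 0.5, or None if never reached."""
    idx = np.nonzero(curve.survival <= 0.5 + 1e-12)[0]
    if idx.size == 0:
        return None
    return float(curve.event_times[idx[0]])


def km_rate_at(curve: KMCurve, t: float) -> float:
    """S(t) by right-continuous step lookup; S(t)=1 before the first event."""
    if t < 0:
        raise ValueError("t must be non-negative")
    idx = np.searchsorted(curve.event_times, t, side="right") - 1
    if idx < 0:
        return 1.0
    return float(curve.survival[idx])


# ---------------------------------------------------------------------------
# log-rank test
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class LogRankResult:
    chi_square: float
    df: int
    p: float


def logrank_test(times, events, groups) -> LogRankResult:
    """k-group log-rank test (observed minus expected, hypergeometric
    variance), chi-square reference with k-1 degrees of freedom."""
    t, d = _check_times_events(times, events)
    g = np.asarray(groups)
    if g.shape != t.shape:
        raise ValueError("groups must match times in length")
    labels, gidx = np.unique(g, return_inverse=True)
    k = labels.size
    if k < 2:
        raise ValueError("need at least two groups")
    for j in range(k):
        if np.sum(gidx == j) == 0:  # pragma: no cover - unique guarantees >0
            raise ValueError("empty group")

    ev_times = np.unique(t[d == 1])
    O = np.zeros(k)
    E = np.zeros(k)
    V = np.zeros((k, k))
    for u in ev_times:
        at_risk_mask = t >= u
        n_j = float(np.sum(at_risk_mask))
        d_j = float(np.sum((t == u) & (d == 1)))
        n_ij = np.bincount(gidx[at_risk_mask], minlength=k).astype(float)
        d_ij = np.bincount(gidx[(t == u) & (d == 1)], minlength=k).astype(float)
        O += d_ij
        E += d_j * n_ij / n_j
        if n_j > 1:
            frac = n_ij / n_j
            hyper = d_j * (n_j - d_j) / (n_j - 1.0)
            V += hyper * (np.diag(frac) - np.outer(frac, frac))
    z = (O - E)[:-1]
    Vsub = V[:-1, :-1]
    try:
        chi2 = float(z @ np.linalg.solve(Vsub, z))
    except np.linalg.LinAlgError:
        chi2 = float(z @ np.linalg.pinv(Vsub) @ z)
    chi2 = max(chi2, 0.0)
    df = k - 1
    p = float(_st.chi2.sf(chi2, df))
    return LogRankResult(chi_square=chi2, df=df, p=p)


# ---------------------------------------------------------------------------
# Cox proportional hazards (Efron ties, Newton–Raphson)
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class CoxResult:
    names: tuple[str, ...]
    coef: np.ndarray
    hazard_ratio: np.ndarray
    se: np.ndarray
    ci95_low: np.ndarray
    ci95_high: np.ndarray
    wald_p: np.ndarray
    log_likelihood: float
    iterations: int
    converged: bool

    def as_dict(self) -> dict:
        out = {}
        for i, name in enumerate(self.names):
            out[name] = {
                "coef": float(self.coef[i]),
                "hr": float(self.hazard_ratio[i]),
                "se": float(self.se[i]),
                "ci95": [float(self.ci95_low[i]), float(self.ci95_high[i])],
                "p": float(self.wald_p[i]),
            }
        return out


def _cox_loglik_grad_hess(beta, X, t, d):
    """Efron partial log-likelihood with gradient and Hessian.

    Rows must be sorted by ascending time.  Risk sets are suffix sums; each
    distinct event time contributes D Efron terms with the tied-event sums
    progressively discounted.
    """
    n, p = X.shape
    eta = X @ beta
    # protect against overflow in exp for wild steps
    eta = np.clip(eta, -500, 500)
    w = np.exp(eta)
    wx = w[:, None] * X
    wxx = wx[:, :, None] * X[:, None, :]

    # suffix (risk-set) cumulative sums
    S0 = np.cumsum(w[::-1])[::-1]
    S1 = np.cumsum(wx[::-1], axis=0)[::-1]
    S2 = np.cumsum(wxx[::-1], axis=0)[::-1]

    ll = 0.0
    grad = np.zeros(p)
    hess = np.zeros((p, p))

    i = 0
    while i < n:
        j = i
        while j < n and t[j] == t[i]:
            j += 1
        ev = np.arange(i, j)[d[i:j] == 1]
        D = ev.size
        if D > 0:
            s0r, s1r, s2r = S0[i], S1[i], S2[i]
            s0d = np.sum(w[ev])
            s1d = np.sum(wx[ev], axis=0)
            s2d = np.sum(wxx[ev], axis=0)
            ll += float(np.sum(eta[ev]))
            grad += np.sum(X[ev], axis=0)
            for l in range(D):
                f = l / D
                a0 = s0r - f * s0d
                a1 = s1r - f * s1d
                a2 = s2r - f * s2d
                ll -= np.log(a0)
                grad -= a1 / a0
                hess -= a2 / a0 - np.outer(a1, a1) / (a0 * a0)
        i = j
    return ll, grad, -hess  # return observed information (positive definite)


def cox_fit(
    X,
    times,
    events,
    names: Sequence[str] | None = None,
    max_iter: int = 50,
    score_tol: float = 1e-8,
    ll_tol: float = 1e-10,
) -> CoxResult:
    """Fit a Cox proportional-hazards model.

    Newton–Raphson maximization of the Efron partial likelihood with
    step-halving; Wald 95% CIs as exp(coef +/- 1.96 se).

    Raises ``ValueError`` for constant covariates or data with no events.
    A monotone likelihood (perfect separation) surfaces as
    ``converged=False`` with inflated coefficients.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] == 1 and X.shape[1] > 1 and np.asarray(times).size == X.shape[1]:
        X = X.T
    t, d = _check_times_events(times, events)
    if X.shape[0] != t.size:
        raise ValueError("X rows must match number of subjects")
    if d.sum() < 1:
        raise ValueError("need at least one event")
    p = X.shape[1]
    if names is None:
        names = tuple(f"x{i}" for i in range(p))
    names = tuple(names)
    for i in range(p):
        if np.ptp(X[:, i]) == 0:
            raise ValueError(f"covariate {names[i]!r} is constant")

    order = np.argsort(t, kind="stable")
    Xs, ts, ds = X[order], t[order], d[order]

    beta = np.zeros(p)
    ll, grad, info = _cox_loglik_grad_hess(beta, Xs, ts, ds)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(info, grad, rcond=None)[0]
        # step halving keeps the likelihood from decreasing
        new_beta = beta + step
        new_ll, new_grad, new_info = _cox_loglik_grad_hess(new_beta, Xs, ts, ds)
        halvings = 0
        while new_ll < ll and halvings < 10:
            step *= 0.5
            halvings += 1
            new_beta = beta + step
            new_ll, new_grad, new_info = _cox_loglik_grad_hess(new_beta, Xs, ts, ds)
        rel = abs(new_ll - ll) / (abs(ll) + 1e-300)
        beta, ll, grad, info = new_beta, new_ll, new_grad, new_info
        if np.max(np.abs(grad)) < score_tol or rel < ll_tol:
            converged = True
            break

    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(info)
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    z = np.divide(beta, se, out=np.zeros_like(beta), where=se > 0)
    wald_p = 2.0 * _st.norm.sf(np.abs(z))
    with np.errstate(over="ignore"):  # inf CI bound under near-separation
        lo = np.exp(beta - 1.96 * se)
        hi = np.exp(beta + 1.96 * se)
    return CoxResult(
        names=names,
        coef=beta,
        hazard_ratio=np.exp(beta),
        se=se,
        ci95_low=lo,
        ci95_high=hi,
        wald_p=wald_p,
        log_likelihood=float(ll),
        iterations=it,
        converged=converged,
    )


def cox_score_test(X, times, events) -> float:
    """Score (Rao) test statistic at beta = 0.

    For a single binary covariate on tie-free data this equals the
    two-group log-rank chi-square exactly.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] == 1 and np.asarray(times).size == X.shape[1]:
        X = X.T
    t, d = _check_times_events(times, events)
    order = np.argsort(t, kind="stable")
    _, grad, info = _cox_loglik_grad_hess(np.zeros(X.shape[1]), X[order], t[order], d[order])
    try:
        return float(grad @ np.linalg.solve(info, grad))
    except np.linalg.LinAlgError:
        return float(grad @ np.linalg.pinv(info) @ grad)


# ---------------------------------------------------------------------------
# recurrence timing & generic group comparisons
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class RecurrenceTimingRule:
    """Very-early recurrence is RFS < ``very_early_max`` months; late is
    RFS >= ``late_min``; in between is early."""

    very_early_max: float = 6.0
    late_min: float = 12.0

    def __post_init__(self):
        if not self.very_early_max < self.late_min:
            raise ValueError("very_early_max must be < late_min")


def classify_recurrence_timing(
    rfs_months: float, recurred: int | bool, rule: RecurrenceTimingRule = RecurrenceTimingRule()
) -> str:
    if rfs_months < 0:
        raise ValueError("rfs_months must be non-negative")
    if not recurred:
        return "none"
    if rfs_months < rule.very_early_max:
        return "very_early"
    if rfs_months < rule.late_min:
        return "early"
    return "late"


def chi_square_test(table) -> tuple[float, int, float]:
    """Pearson chi-square on an r x c contingency table, no continuity
    correction.  Returns (statistic, df, p)."""
    O = np.asarray(table, dtype=float)
    if O.ndim != 2 or O.shape[0] < 2 or O.shape[1] < 2:
        raise ValueError("table must be at least 2x2")
    if np.any(O < 0):
        raise ValueError("cells must be non-negative")
    rows = O.sum(axis=1)
    cols = O.sum(axis=0)
    if np.any(rows == 0) or np.any(cols == 0):
        raise ValueError("zero row/column margin")
    E = np.outer(rows, cols) / O.sum()
    stat = float(np.sum((O - E) ** 2 / E))
    df = (O.shape[0] - 1) * (O.shape[1] - 1)
    p = float(_st.chi2.sf(stat, df))
    return stat, df, p


def compare_continuous(x, y, method: str = "t") -> tuple[float, float]:
    """Two-sample comparison: Welch t test (``"t"``) or Mann–Whitney
    rank-sum (``"wilcoxon"``), two-sided.  Returns (statistic, p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs >= 2 observations")
    if method == "t":
        if np.ptp(x) == 0 and np.ptp(y) == 0:
            raise ValueError("degenerate (zero-variance) samples for t test")
        res = _st.ttest_ind(x, y, equal_var=False)
        return float(res.statistic), float(res.pvalue)
    if method == "wilcoxon":
        has_ties = np.unique(np.concatenate([x, y])).size < x.size + y.size
        res = _st.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic" if has_ties else "exact"
        )
        return float(res.statistic), float(res.pvalue)
    raise ValueError(f"unknown method {method!r}")
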