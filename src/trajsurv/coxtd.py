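"""Cox proportional hazards with time-varying covariates.

Operates on counting-process tables of half-open ``(start, stop]``
intervals: the partial likelihood is maximized by Newton-Raphson with
step-halving, ties handled by the Breslow approximation (Efron available),
and Wald standard errors taken from the inverse observed information.

Two expansions build the tables the comparison methods need:

* :func:`expand_lvcf` — last-value-carried-forward: each observed
  measurement is carried on the interval up to the next measurement (or
  the end of follow-up), the classic time-dependent covariate analysis;
* :func:`expand_predicted` — intervals broken at every event time, with
  the covariate set to the mixed-model predicted trajectory at each
  break, so every risk set sees each at-risk subject's predicted value at
  that event time (the second stage of the two-step approach).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_data import CountingProcessTable
from .lme import LMEFit, predict_trajectory

__all__ = ["CoxFit", "fit_cox_td", "partial_loglik", "expand_lvcf", "expand_predicted"]


@dataclass
class CoxFit:
    coefficients: dict
    se: dict
    information: np.ndarray
    loglik: float
    iterations: int
    converged: bool
    extra: dict = field(default_factory=dict)

    @property
    def estimates(self) -> dict:  # FitResult-compatible surface
        return dict(self.coefficients)

    @property
    def standard_errors(self) -> dict:
        return dict(self.se)


def _prepare(table: CountingProcessTable):
    df = table.data
    X = df[list(table.covariate_names)].to_numpy(dtype=float)
    start = df["start"].to_numpy(dtype=float)
    stop = df["stop"].to_numpy(dtype=float)
    status = df["status"].to_numpy(dtype=int)
    ev_times = np.unique(stop[status == 1])
    if len(ev_times) == 0:
        raise ValueError("no events in table; Cox fit is undefined")
    groups = []
    for t in ev_times:
        dead = np.flatnonzero((status == 1) & (stop == t))
        risk = np.flatnonzero((start < t) & (t <= stop))
        groups.append((dead, risk))
    return X, groups


def _pl_quantities(beta, X, groups, ties):
    """(log partial likelihood, score, information) in one pass."""
    p = X.shape[1]
    eta = X @ beta
    shift = eta.max() if len(eta) else 0.0
    w = np.exp(eta - shift)
    ll, score, info = 0.0, np.zeros(p), np.zeros((p, p))
    for dead, risk in groups:
        d = len(dead)
        Xr, wr = X[risk], w[risk]
        s0 = wr.sum()
        s1 = wr @ Xr
        s2 = (wr[:, None] * Xr).T @ Xr
        ll += eta[dead].sum()
        if ties == "breslow" or d == 1:
            ll -= d * (np.log(s0) + shift)
            mean = s1 / s0
            score += X[dead].sum(axis=0) - d * mean
            info += d * (s2 / s0 - np.outer(mean, mean))
        elif ties == "efron":
            wd = w[dead]
            Xd = X[dead]
            s0d = wd.sum()
            s1d = wd @ Xd
            s2d = (wd[:, None] * Xd).T @ Xd
            for j in range(d):
                f = j / d
                a0 = s0 - f * s0d
                a1 = s1 - f * s1d
                a2 = s2 - f * s2d
                ll -= np.log(a0) + shift
                mean = a1 / a0
                score += Xd.sum(axis=0) / d - mean
                info += a2 / a0 - np.outer(mean, mean)
        else:
            raise ValueError(f"unknown tie method {ties!r}")
    return ll, score, info


def partial_loglik(table: CountingProcessTable, beta, ties: str = "breslow") -> float:
    """Log partial likelihood at ``beta`` (covariate order = covariate_names)."""
    X, groups = _prepare(table)
    ll, _, _ = _pl_quantities(np.asarray(beta, dtype=float), X, groups, ties)
    return float(ll)


def fit_cox_td(
    table: CountingProcessTable,
    ties: str = "breslow",
    max_iter: int = 50,
    tol: float = 1e-8,
) -> CoxFit:
    """Newton-Raphson from beta = 0 with step-halving.

    Convergence requires max |score| <= ``tol``.  A monotone likelihood
    (perfect separation) is reported as ``converged=False`` with the last
    iterate, matching standard survival software behaviour.
    """
    X, groups = _prepare(table)
    p = X.shape[1]
    beta = np.zeros(p)
    ll, score, info = _pl_quantities(beta, X, groups, ties)
    it = 0
    converged = False
    for it in range(1, max_iter + 1):
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            break
        new_beta = beta + step
        new_ll, new_score, new_info = _pl_quantities(new_beta, X, groups, ties)
        halvings = 0
        while (not np.isfinite(new_ll) or new_ll < ll - 1e-12) and halvings < 30:
            step *= 0.5
            new_beta = beta + step
            new_ll, new_score, new_info = _pl_quantities(new_beta, X, groups, ties)
            halvings += 1
        beta, ll, score, info = new_beta, new_ll, new_score, new_info
        if np.max(np.abs(score)) <= tol:
            converged = True
            break
    if converged and np.max(np.abs(beta)) > 15.0:
        # score can underflow while the likelihood is monotone and the
        # coefficient diverges (perfect separation); flag it
        converged = False
    if not converged:
        warnings.warn(
            "Cox Newton-Raphson did not converge (possible monotone "
            "likelihood); returning last iterate",
            RuntimeWarning,
            stacklevel=2,
        )
    try:
        cov = np.linalg.inv(info)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        se = np.full(p, np.nan)
    names = list(table.covariate_names)
    return CoxFit(
        coefficients=dict(zip(names, beta)),
        se=dict(zip(names, se)),
        information=info,
        loglik=float(ll),
        iterations=it,
        converged=converged,
    )


def _surv_map(survival):
    return {r.subject_id: r for r in survival}


def expand_lvcf(panels, survival) -> CountingProcessTable:
    """Last-value-carried-forward counting-process expansion.

    Each measurement Y_ij is carried on ``(t_ij, t_{i,j+1}]``; the last
    interval ends at the follow-up time T_i with the event status.  A
    measurement coincident with T_i is not used (strict carry-forward).
    Requires a baseline (t = 0) measurement for every subject.
    """
    surv = _surv_map(survival)
    rows = []
    for pnl in panels:
        if abs(pnl.times[0]) > 1e-12:
            raise ValueError(f"subject {pnl.subject_id}: no baseline (t=0) measurement")
        rec = surv[pnl.subject_id]
        T = rec.time
        keep = pnl.times < T - 1e-12
        t_used = pnl.times[keep]
        y_used = pnl.values[keep]
        if len(t_used) == 0:  # T at or before baseline: carry the baseline value
            t_used, y_used = pnl.times[:1], pnl.values[:1]
        stops = np.append(t_used[1:], T)
        starts = t_used
        for j in range(len(stops)):
            rows.append(
                (pnl.subject_id, starts[j], stops[j],
                 int(rec.event) if j == len(stops) - 1 else 0,
                 y_used[j], pnl.age, pnl.sex)
            )
    df = pd.DataFrame(rows, columns=["id", "start", "stop", "status", "value", "age", "sex"])
    return CountingProcessTable(df, ("value", "age", "sex"))


def expand_predicted(fit: LMEFit, panels, survival) -> CountingProcessTable:
    """Predicted-trajectory expansion broken at every distinct event time.

    On each interval the covariate is the predicted trajectory evaluated
    at the interval's stop, so the risk set at an event time t sees each
    at-risk subject's prediction at exactly t.
    """
    surv = _surv_map(survival)
    ev_times = np.unique([r.time for r in survival if r.event == 1])
    rows = []
    for pnl in panels:
        rec = surv[pnl.subject_id]
        T = rec.time
        stops = ev_times[ev_times <= T].tolist()
        if not stops or stops[-1] < T:
            stops.append(T)
        preds = predict_trajectory(fit, pnl.subject_id, np.asarray(stops))
        preds = np.atleast_1d(preds)
        start = 0.0
        for j, stp in enumerate(stops):
            rows.append(
                (pnl.subject_id, start, stp,
                 int(rec.event) if j == len(stops) - 1 else 0,
                 float(preds[j]), pnl.age, pnl.sex)
            )
            start = stp
    df = pd.DataFrame(rows, columns=["id", "start", "stop", "status", "value", "age", "sex"])
    return CountingProcessTable(df, ("value", "age", "sex"))
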