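"""Random-intercept/random-slope Gaussian linear mixed model.

Measurement model:  Y_ij = (mu1 + b1_i) + (mu2 + b2_i) * t_ij
                           + beta_age * Age_i + eps_ij,
with (b1, b2) ~ MVN(0, G) and eps ~ N(0, sigma2), so marginally
y_i ~ N(X_i beta, V_i),  V_i = Z_i G Z_i' + sigma2 * I.

Estimation is marginal maximum likelihood: the variance parameters
(Cholesky factor of G with log-diagonal, log sigma2) are optimized by
quasi-Newton while the fixed effects are profiled out by generalized least
squares at every evaluation.  All per-subject linear algebra reduces to
2x2 Woodbury identities, vectorized across subjects, so fits scale to
thousands of subjects.  Empirical-Bayes (BLUP) predictions
b_i = G Z_i' V_i^{-1} (y_i - X_i beta) are computed at the optimum.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .core_data import LongPanel

__all__ = ["LMEFit", "fit_lme", "predict_blups", "predict_trajectory"]

_LOG2PI = math.log(2.0 * math.pi)
# bounds on log-scale variance parameters keep V_i invertible
_LOG_SD_LO, _LOG_SD_HI = -15.0, 6.0
_LOG_S2_LO, _LOG_S2_HI = -30.0, 12.0


class IdentifiabilityError(ValueError):
    pass


@dataclass
class LMEFit:
    """Marginal-ML fit of the growth-curve model."""

    fixed: np.ndarray              # (mu1, mu2[, beta_age])
    fixed_names: tuple
    G_hat: np.ndarray
    sigma2_hat: float
    blups: dict                    # subject_id -> (b1, b2) deviation
    loglik: float
    vcov_fixed: np.ndarray
    converged: bool
    iterations: int
    include_age: bool
    ages: dict = field(default_factory=dict)
    loglik_path: np.ndarray | None = None

    @property
    def estimates(self) -> dict:
        out = dict(zip(self.fixed_names, self.fixed))
        out.update(
            sigma2=self.sigma2_hat,
            G11=self.G_hat[0, 0],
            G12=self.G_hat[0, 1],
            G22=self.G_hat[1, 1],
        )
        return out

    @property
    def standard_errors(self) -> dict:
        return dict(zip(self.fixed_names, np.sqrt(np.diag(self.vcov_fixed))))


class _Stacked:
    """Per-subject sufficient statistics for the 2x2 Woodbury algebra."""

    def __init__(self, panels, include_age: bool):
        n = len(panels)
        self.ids = [p.subject_id for p in panels]
        self.ages = np.array([p.age for p in panels])
        self.include_age = include_age
        self.m = np.array([p.m for p in panels], dtype=float)
        self.N = float(self.m.sum())
        # Z'Z blocks
        St = np.array([p.times.sum() for p in panels])
        Stt = np.array([(p.times**2).sum() for p in panels])
        Sy = np.array([p.values.sum() for p in panels])
        Sty = np.array([(p.times * p.values).sum() for p in panels])
        self.Syy = np.array([(p.values**2).sum() for p in panels])
        self.ZtZ = np.empty((n, 2, 2))
        self.ZtZ[:, 0, 0] = self.m
        self.ZtZ[:, 0, 1] = self.ZtZ[:, 1, 0] = St
        self.ZtZ[:, 1, 1] = Stt
        self.Zty = np.stack([Sy, Sty], axis=1)
        # X = [1, t] or [1, t, age]; X'Z and X'y are Z-moments scaled by age
        p_fix = 3 if include_age else 2
        self.p = p_fix
        self.XtZ = np.empty((n, p_fix, 2))
        self.XtZ[:, :2, :] = self.ZtZ
        self.Xty = np.empty((n, p_fix))
        self.Xty[:, :2] = self.Zty
        if include_age:
            self.XtZ[:, 2, :] = self.ZtZ[:, 0, :] * self.ages[:, None]
            self.Xty[:, 2] = Sy * self.ages
        self.XtX = _outer_expand(self.ZtZ, self.ages, include_age)

    def distinct_times(self, panels):
        return np.unique(np.concatenate([p.times for p in panels]))


def _outer_expand(ZtZ, ages, include_age):
    n = ZtZ.shape[0]
    p = 3 if include_age else 2
    XtX = np.empty((n, p, p))
    XtX[:, :2, :2] = ZtZ
    if include_age:
        XtX[:, 2, :2] = ZtZ[:, 0, :] * ages[:, None]
        XtX[:, :2, 2] = XtX[:, 2, :2]
        XtX[:, 2, 2] = ZtZ[:, 0, 0] * ages**2
    return XtX


def _unpack(theta):
    a, b, c, ls2 = theta
    L = np.array([[math.exp(a), 0.0], [b, math.exp(c)]])
    G = L @ L.T
    # log det G = 2(a + c) exactly (triangular factor), immune to underflow
    return G, math.exp(ls2), 2.0 * (a + c)


def _inv2(Mats):
    """Batched 2x2 inverse."""
    det = Mats[:, 0, 0] * Mats[:, 1, 1] - Mats[:, 0, 1] * Mats[:, 1, 0]
    inv = np.empty_like(Mats)
    inv[:, 0, 0] = Mats[:, 1, 1]
    inv[:, 1, 1] = Mats[:, 0, 0]
    inv[:, 0, 1] = -Mats[:, 0, 1]
    inv[:, 1, 0] = -Mats[:, 1, 0]
    return inv / det[:, None, None], det


def _profile_pieces(st: _Stacked, G, s2, logdetG):
    """K_i = (s2*G^{-1} + Z'Z)^{-1} and the profiled GLS quantities."""
    Ginv = np.linalg.inv(G)
    Kinv = s2 * Ginv[None, :, :] + st.ZtZ
    K, detKinv = _inv2(Kinv)
    if np.any(detKinv <= 0):
        raise np.linalg.LinAlgError("indefinite K")
    # log|V_i| = m_i log s2 + log det(I + G Z'Z / s2)
    #          = (m_i - 2) log s2 + log det(s2 G^{-1} + Z'Z) + log det G
    logdetV = (st.m - 2.0) * math.log(s2) + np.log(detKinv) + logdetG
    # X'V^{-1}X = (X'X - X'Z K Z'X)/s2, etc.
    XtZK = np.einsum("nij,njk->nik", st.XtZ, K)
    XtVX = (st.XtX - np.einsum("nik,njk->nij", XtZK, st.XtZ)) / s2
    XtVy = (st.Xty - np.einsum("nik,nk->ni", XtZK, st.Zty)) / s2
    ytVy = (st.Syy - np.einsum("ni,nij,nj->n", st.Zty, K, st.Zty)) / s2
    return K, logdetV, XtVX.sum(axis=0), XtVy.sum(axis=0), ytVy.sum()


def _neg_profile_loglik(theta, st: _Stacked, want_beta=False):
    try:
        G, s2, logdetG = _unpack(theta)
        K, logdetV, A, bvec, yy = _profile_pieces(st, G, s2, logdetG)
        beta = np.linalg.solve(A, bvec)
    except (np.linalg.LinAlgError, ValueError, OverflowError):
        return (np.inf, None) if want_beta else np.inf
    quad = yy - 2.0 * bvec @ beta + beta @ A @ beta
    ll = -0.5 * (st.N * _LOG2PI + logdetV.sum() + quad)
    if not np.isfinite(ll):
        return (np.inf, None) if want_beta else np.inf
    return (-ll, beta) if want_beta else -ll


def _moment_start(panels, include_age):
    """OLS per-subject lines -> moment estimates of (G, sigma2)."""
    inter, slope, resid_ss, resid_df = [], [], 0.0, 0
    for p in panels:
        if p.m >= 2:
            X = np.column_stack([np.ones(p.m), p.times])
            coef, res, *_ = np.linalg.lstsq(X, p.values, rcond=None)
            inter.append(coef[0])
            slope.append(coef[1])
            if p.m > 2 and len(res):
                resid_ss += float(res[0])
                resid_df += p.m - 2
    s2 = resid_ss / resid_df if resid_df > 0 else np.var(
        np.concatenate([p.values for p in panels])
    ) * 0.1
    s2 = max(s2, 1e-6)
    if len(inter) >= 2:
        C = np.cov(np.array([inter, slope]))
        g11 = max(C[0, 0] - s2, 1e-4)
        g22 = max(C[1, 1] - s2 / 100.0, 1e-6)
    else:
        g11, g22 = 0.25, 1e-3
    a = 0.5 * math.log(g11)
    c = 0.5 * math.log(g22)
    return np.array([a, 0.0, c, math.log(s2)])


def fit_lme(panels, include_age: bool = True, reml: bool = False) -> LMEFit:
    """Marginal-ML fit; ``reml=True`` switches to the REML criterion.

    Raises :class:`IdentifiabilityError` when fewer than 2 subjects or
    fewer than 2 distinct measurement times are available.
    """
    if len(panels) < 2:
        raise IdentifiabilityError("need at least 2 subjects")
    st = _Stacked(panels, include_age)
    if len(st.distinct_times(panels)) < 2:
        raise IdentifiabilityError("need at least 2 distinct measurement times")

    bounds = [(_LOG_SD_LO, _LOG_SD_HI), (-50.0, 50.0),
              (_LOG_SD_LO, _LOG_SD_HI), (_LOG_S2_LO, _LOG_S2_HI)]
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])

    def objective(theta):
        # smooth quadratic barrier instead of hard L-BFGS-B bounds (the
        # bounded line search can stall); inside the box it is untouched
        pen = 1e4 * (
            np.square(np.clip(theta - hi, 0.0, None)).sum()
            + np.square(np.clip(lo - theta, 0.0, None)).sum()
        )
        nll = _neg_profile_loglik(np.clip(theta, lo, hi), st)
        if reml and np.isfinite(nll):
            G, s2, logdetG = _unpack(np.clip(theta, lo, hi))
            _, _, A, _, _ = _profile_pieces(st, G, s2, logdetG)
            nll += 0.5 * np.linalg.slogdet(A)[1]
        return nll + pen

    start = _moment_start(panels, include_age)
    starts = [start, start + np.array([0.5, 0.1, 0.5, 0.5])]
    best = None
    for x0 in starts:
        res = optimize.minimize(
            objective, np.clip(x0, lo, hi), method="L-BFGS-B", jac="3-point",
            options={"maxiter": 500, "ftol": 1e-13, "gtol": 1e-8},
        )
        if best is None or res.fun < best.fun:
            best = res
    best.x = np.clip(best.x, lo, hi)

    G, s2, logdetG = _unpack(best.x)
    nll, beta = _neg_profile_loglik(best.x, st, want_beta=True)
    _, _, A, bvec, _ = _profile_pieces(st, G, s2, logdetG)
    vcov = np.linalg.inv(A)

    # BLUPs: b_i = G Z' V^{-1} r_i, with Z'V^{-1}r = (Z'r - Z'Z K Z'r)/s2
    K, *_ = _profile_pieces(st, G, s2, logdetG)
    Ztr = st.Zty - np.einsum("npj,p->nj", st.XtZ, beta)
    ZtVr = (Ztr - np.einsum("nij,njk,nk->ni", st.ZtZ, K, Ztr)) / s2
    b = np.einsum("ij,nj->ni", G, ZtVr)
    blups = {sid: (float(b[i, 0]), float(b[i, 1])) for i, sid in enumerate(st.ids)}

    h = 1e-5
    grad = np.array([
        (objective(best.x + h * e) - objective(best.x - h * e)) / (2 * h)
        for e in np.eye(4)
    ])
    at_bound = np.array([
        x <= lo + 1e-9 or x >= hi - 1e-9 for x, (lo, hi) in zip(best.x, bounds)
    ])
    # convergence is judged by the (scaled) profile-likelihood gradient;
    # the optimizer's own status can report line-search noise at the optimum
    gtol = 1e-3 * max(1.0, abs(nll))
    converged = bool(np.all((np.abs(grad) <= gtol) | at_bound))
    names = ("mu1", "mu2", "beta_age") if include_age else ("mu1", "mu2")
    return LMEFit(
        fixed=beta,
        fixed_names=names,
        G_hat=G,
        sigma2_hat=s2,
        blups=blups,
        loglik=-nll,
        vcov_fixed=vcov,
        converged=converged,
        iterations=int(best.nit),
        include_age=include_age,
        ages={p.subject_id: p.age for p in panels},
    )


def marginal_loglik(panels, fixed, G, sigma2, include_age: bool = True) -> float:
    """Dense-matrix evaluation of the marginal Gaussian log-likelihood.

    Deliberately naive (builds each V_i explicitly); used to verify the
    Woodbury fast path and by the joint model's gamma = 0 factorization.
    """
    fixed = np.asarray(fixed, dtype=float)
    ll = 0.0
    for p in panels:
        Z = np.column_stack([np.ones(p.m), p.times])
        X = Z if not include_age else np.column_stack([Z, np.full(p.m, p.age)])
        V = Z @ G @ Z.T + sigma2 * np.eye(p.m)
        r = p.values - X @ fixed
        sign, logdet = np.linalg.slogdet(V)
        ll += -0.5 * (p.m * _LOG2PI + logdet + r @ np.linalg.solve(V, r))
    return float(ll)


def predict_blups(fit: LMEFit, panels) -> dict:
    """Look up the empirical-Bayes (b1, b2) deviations for ``panels``."""
    out = {}
    for p in panels:
        if p.subject_id not in fit.blups:
            raise KeyError(f"subject {p.subject_id} was not part of the fit")
        out[p.subject_id] = fit.blups[p.subject_id]
    return out


def predict_trajectory(fit: LMEFit, subject_id: str, t) -> float:
    """Predicted trajectory (mu1+b1) + (mu2+b2)*t + beta_age*Age at time t."""
    if subject_id not in fit.blups:
        raise KeyError(f"subject {subject_id} was not part of the fit")
    b1, b2 = fit.blups[subject_id]
    mu1, mu2 = fit.fixed[0], fit.fixed[1]
    val = (mu1 + b1) + (mu2 + b2) * np.asarray(t, dtype=float)
    if fit.include_age:
        val = val + fit.fixed[2] * fit.ages[subject_id]
    return float(val) if np.ndim(val) == 0 else val
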