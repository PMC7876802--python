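"""Closed-form simulation of joint longitudinal-survival data.

Each subject carries a linear latent trajectory

    phi(t) = U1 + U2*t + beta_age_long * Age,     (U1, U2) ~ MVN(mu, G)

observed with Gaussian noise at scheduled exam times, and a latent event
time S whose cumulative hazard has the plug-in form

    H(t) = lam * t^nu * exp{ X'beta + gamma * phi(t) },

with X'beta = alpha_age*Age + alpha_sex*Sex (the trajectory's own age term
is folded into the exponent through gamma*phi).  Because phi is linear in
t, H(t) = -log M can be inverted in closed form with the principal branch
of the Lambert W function; nu = 1 recovers the Exponential baseline.

The defaults emulate a Framingham-style panel: 6 exams at 4-year spacing,
triglyceride-like log-scale trajectories, uniform(25, 30)-year censoring
with administrative cut-off at 30 years.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import integrate, special

from .core_data import LongPanel, SurvivalRecord, TrueLatentState

__all__ = [
    "GenParams",
    "lambert_w0",
    "survival_time_exponential",
    "survival_time_weibull",
    "generate_dataset",
    "calibrate_lambda",
]

_INV_E = -math.exp(-1.0)
# below this, gamma*U2 (or gamma*U2/nu) is treated as zero and the
# Exponential/Weibull inverse-CDF limit is used (Lambert argument underflow)
_LINEAR_TOL = 1e-10

MAX_FOLLOW_UP = 30.0


@dataclass
class GenParams:
    """Generation parameters; defaults are the Framingham-like panel.

    ``gamma`` is the link (log hazard ratio per trajectory unit), ``lam``
    and ``nu`` the Weibull baseline scale/shape, ``beta_age_long`` the age
    coefficient inside the trajectory.
    """

    mu: np.ndarray = field(default_factory=lambda: np.array([4.250, 0.250]))
    G: np.ndarray = field(
        default_factory=lambda: np.array([[0.29, -0.00465], [-0.00465, 0.000320]])
    )
    sigma2: float = 0.1161
    alpha_age: float = 0.050
    alpha_sex: float = -0.500
    beta_age_long: float = 0.050
    gamma: float = 0.0
    lam: float = 1e-5
    nu: float = 1.5
    exam_times: np.ndarray = field(
        default_factory=lambda: np.array([0.0, 4.0, 8.0, 12.0, 16.0, 20.0])
    )
    cens_low: float = 25.0
    cens_high: float = 30.0
    n: int = 100
    seed: int = 0
    # baseline covariate marginals (FHS-like)
    age_mean: float = 43.3
    age_sd: float = 9.58
    age_bounds: tuple = (25.0, 75.0)
    p_female: float = 0.512

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=float)
        self.G = np.asarray(self.G, dtype=float)
        self.exam_times = np.asarray(self.exam_times, dtype=float)
        if self.G.shape != (2, 2) or not np.allclose(self.G, self.G.T):
            raise ValueError("G must be a symmetric 2x2 matrix")
        if np.any(np.linalg.eigvalsh(self.G) < -1e-12):
            raise ValueError("G must be positive semi-definite")
        if self.sigma2 < 0:
            raise ValueError("sigma2 must be >= 0")
        if self.lam <= 0 or self.nu <= 0:
            raise ValueError("lam and nu must be > 0")
        if not self.cens_low < self.cens_high:
            raise ValueError("need cens_low < cens_high")
        if self.exam_times[0] != 0 or np.any(np.diff(self.exam_times) <= 0):
            raise ValueError("exam_times must start at 0 and strictly increase")


def lambert_w0(x):
    """Principal branch W0 of the Lambert W function, real-valued.

    Accepts scalars or arrays with every element >= -1/e; returns w with
    w*exp(w) = x.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < _INV_E * (1 + 1e-12) - 1e-300):
        raise ValueError("lambert_w0 requires x >= -1/e")
    w = special.lambertw(np.clip(x, _INV_E, None), k=0)
    return np.real(w) if w.ndim else float(np.real(w))


def survival_time_exponential(U1, U2, xbeta, gamma, lam, M):
    """Latent event time under the Exponential (nu = 1) plug-in hazard.

    Solves lam*T*exp{xbeta + gamma*(U1 + U2*T)} = -log M for T on the
    principal Lambert branch.  Returns ``inf`` when the cumulative hazard
    is bounded below -log M (possible for gamma*U2 < 0: the event is
    unreachable and the subject is censored).
    """
    return survival_time_weibull(U1, U2, xbeta, gamma, lam, 1.0, M)


def survival_time_weibull(U1, U2, xbeta, gamma, lam, nu, M):
    """Latent event time under the Weibull plug-in hazard.

    T = (1/c) * W0(c * A),  c = gamma*U2/nu,
    A = (-log M / (lam * exp{xbeta + gamma*U1}))^(1/nu);
    equivalently T solves lam*T^nu*exp{xbeta + gamma*(U1 + U2*T)} = -log M.
    The |c| -> 0 limit is the plain Weibull inverse CDF T = A.
    """
    U1, U2, xbeta, M = np.broadcast_arrays(
        np.asarray(U1, dtype=float),
        np.asarray(U2, dtype=float),
        np.asarray(xbeta, dtype=float),
        np.asarray(M, dtype=float),
    )
    if np.any((M <= 0) | (M >= 1)):
        raise ValueError("M must lie strictly in (0, 1)")
    if lam <= 0 or nu <= 0:
        raise ValueError("lam and nu must be > 0")
    c = gamma * U2 / nu
    A = (-np.log(M) / (lam * np.exp(xbeta + gamma * U1))) ** (1.0 / nu)
    T = np.where(np.abs(c) < _LINEAR_TOL, A, np.nan)
    gen = np.abs(c) >= _LINEAR_TOL
    if np.any(gen):
        arg = c * A
        reachable = gen & (arg >= _INV_E)
        with np.errstate(invalid="ignore"):
            w = np.real(special.lambertw(np.where(reachable, arg, 0.0)))
            T = np.where(reachable, w / np.where(gen, c, 1.0), T)
        T = np.where(gen & ~reachable, np.inf, T)
    return float(T) if T.ndim == 0 else T


def _draw_baseline(params: GenParams, rng: np.random.Generator, n: int):
    """Age ~ truncated Normal, Sex ~ Bernoulli — FHS-like marginals."""
    lo, hi = params.age_bounds
    a = (lo - params.age_mean) / params.age_sd
    b = (hi - params.age_mean) / params.age_sd
    # inverse-CDF truncation keeps the draw reproducible per subject
    u = rng.uniform(size=n)
    from scipy.stats import norm

    age = params.age_mean + params.age_sd * norm.ppf(
        norm.cdf(a) + u * (norm.cdf(b) - norm.cdf(a))
    )
    sex = (rng.uniform(size=n) < params.p_female).astype(int)
    return age, sex


def generate_dataset(params: GenParams, rng: np.random.Generator | None = None):
    """Simulate ``params.n`` subjects; returns (panels, survival, truths).

    Per subject: draw baseline (Age, Sex) and random effects (U1, U2);
    invert the plug-in cumulative hazard at M ~ U(0,1) for the latent event
    time S; censor at C ~ U(cens_low, cens_high) and administratively at 30
    years; keep exam measurements Y_ij = phi(t_ij) + eps at exam times
    t_ij <= T (t = 0 always observed).
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    n = params.n
    age, sex = _draw_baseline(params, rng, n)
    U = rng.multivariate_normal(params.mu, params.G, size=n)
    M = rng.uniform(size=n)
    C = rng.uniform(params.cens_low, params.cens_high, size=n)
    eps = rng.normal(0.0, math.sqrt(params.sigma2), size=(n, len(params.exam_times)))

    xbeta = (
        params.alpha_age * age
        + params.alpha_sex * sex
        + params.gamma * params.beta_age_long * age
    )
    S = survival_time_weibull(
        U[:, 0], U[:, 1], xbeta, params.gamma, params.lam, params.nu, M
    )
    Ccap = np.minimum(C, MAX_FOLLOW_UP)
    T = np.minimum(S, Ccap)
    delta = (S <= Ccap).astype(int)

    width = len(str(n - 1))
    panels, survs, truths = [], [], []
    for i in range(n):
        sid = f"s{i:0{width}d}"
        keep = params.exam_times <= T[i]
        keep[0] = True  # baseline exam always observed
        t_obs = params.exam_times[keep]
        phi = U[i, 0] + U[i, 1] * t_obs + params.beta_age_long * age[i]
        y = phi + eps[i, keep]
        panels.append(LongPanel(sid, t_obs, y, float(age[i]), int(sex[i])))
        survs.append(SurvivalRecord(sid, float(T[i]), int(delta[i])))
        truths.append(
            TrueLatentState(sid, float(U[i, 0]), float(U[i, 1]), float(M[i]),
                            float(S[i]), float(C[i]))
        )
    return panels, survs, truths


def _censoring_fraction(params: GenParams, lam: float, draws) -> float:
    age, sex, U, M, C = draws
    xbeta = (
        params.alpha_age * age
        + params.alpha_sex * sex
        + params.gamma * params.beta_age_long * age
    )
    S = survival_time_weibull(U[:, 0], U[:, 1], xbeta, params.gamma, lam, params.nu, M)
    Ccap = np.minimum(C, MAX_FOLLOW_UP)
    return float(np.mean(S > Ccap))


def calibrate_lambda(
    params: GenParams,
    target_censoring: float,
    reps: int = 5000,
    seed: int = 0,
    tol: float = 0.02,
    lam_bounds: tuple = (1e-8, 1e3),
) -> float:
    """Baseline scale lambda hitting a target censoring fraction.

    Monte-Carlo bisection on log(lambda) with common random numbers, so the
    result is deterministic given ``seed``.  The censoring fraction is
    monotone decreasing in lambda, which makes bisection valid.
    """
    if not 0 < target_censoring < 1:
        raise ValueError("target censoring must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    age, sex = _draw_baseline(params, rng, reps)
    U = rng.multivariate_normal(params.mu, params.G, size=reps)
    M = rng.uniform(size=reps)
    C = rng.uniform(params.cens_low, params.cens_high, size=reps)
    draws = (age, sex, U, M, C)

    lo, hi = (math.log(b) for b in lam_bounds)
    f_lo = _censoring_fraction(params, math.exp(lo), draws)
    f_hi = _censoring_fraction(params, math.exp(hi), draws)
    # fraction decreases with lambda: f_lo ~ 1, f_hi ~ 0
    if not (f_hi <= target_censoring <= f_lo):
        raise ValueError(
            f"target censoring {target_censoring} unreachable in lambda "
            f"bounds {lam_bounds} (range [{f_hi:.3f}, {f_lo:.3f}])"
        )
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        f_mid = _censoring_fraction(params, math.exp(mid), draws)
        if abs(f_mid - target_censoring) <= 0.25 * tol or hi - lo < 1e-12:
            return math.exp(mid)
        if f_mid > target_censoring:
            lo = mid
        else:
            hi = mid
    return math.exp(0.5 * (lo + hi))


def censoring_fraction_gamma0(params: GenParams, lam: float) -> float:
    """Exact censoring fraction in the gamma = 0, fixed-covariate-free case.

    Used as a quadrature oracle for :func:`calibrate_lambda`:
    P(S > C) = E_C[exp(-lam * C^nu)] with C ~ U(cens_low, cens_high),
    computed by 1-D quadrature (valid only when gamma = 0 and the
    covariate coefficients are zero).
    """
    val, _ = integrate.quad(
        lambda c: math.exp(-lam * c**params.nu),
        params.cens_low,
        min(params.cens_high, MAX_FOLLOW_UP),
    )
    return val / (min(params.cens_high, MAX_FOLLOW_UP) - params.cens_low)
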