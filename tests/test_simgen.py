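"""Lambert-W generator: closed forms, identities, calibration."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import optimize, stats

from trajsurv import simgen
from trajsurv.simgen import (
    GenParams,
    calibrate_lambda,
    generate_dataset,
    lambert_w0,
    survival_time_exponential,
    survival_time_weibull,
)


def newton_lambert(x, tol=1e-14):
    """Independent Newton iteration on w*e^w = x (principal branch)."""
    w = 0.0 if x < 1 else math.log(x)
    for _ in range(100):
        ew = math.exp(w)
        step = (w * ew - x) / (ew * (w + 1) - (w + 2) * (w * ew - x) / (2 * w + 2))
        w -= step
        if abs(step) < tol:
            break
    return w


class TestLambertW:
    def test_fixed_points(self):
        assert lambert_w0(0.0) == 0.0
        assert abs(lambert_w0(math.e) - 1.0) < 1e-14

    def test_against_newton_iteration(self):
        for x in [1.0, 0.25, -0.25, 5.0, 100.0, -1 / math.e + 1e-6]:
            assert abs(lambert_w0(x) - newton_lambert(x)) < 1e-10

    def test_domain_error(self):
        with pytest.raises(ValueError):
            lambert_w0(-1.0)

    @given(st.floats(min_value=-0.36, max_value=1e6))
    @settings(max_examples=200, deadline=None)
    def test_defining_identity(self, x):
        w = lambert_w0(x)
        assert abs(w * math.exp(w) - x) <= 1e-12 * max(1.0, abs(x))


class TestSurvivalTimes:
    def test_exponential_inverse_cdf_limit(self):
        # gamma = 0: plain Exponential inverse CDF
        t = survival_time_exponential(0.0, 0.0, 0.0, 0.0, 1.0, math.exp(-2.0))
        assert abs(t - 2.0) < 1e-12

    def test_weibull_inverse_cdf_limit(self):
        t = survival_time_weibull(0.0, 0.0, 0.0, 0.0, 1.0, 2.0, math.exp(-4.0))
        assert abs(t - 2.0) < 1e-12

    def test_exponential_matches_root_finder(self):
        # lam*T*exp(gamma*U2*T) = -log M with lam=.5, gamma=.2, U2=1, M=.5
        lam, gamma, U2, M = 0.5, 0.2, 1.0, 0.5
        t_closed = survival_time_exponential(0.0, U2, 0.0, gamma, lam, M)
        f = lambda t: lam * t * math.exp(gamma * U2 * t) + math.log(M)
        t_root = optimize.brentq(f, 1e-12, 100.0, xtol=1e-14)
        assert abs(t_closed - t_root) < 1e-10
        assert abs(t_closed - 1.110) < 5e-3

    def test_weibull_matches_bisection(self):
        lam, nu, gamma, U1, U2, M = 0.1, 1.5, 0.5, 1.0, 0.1, 0.5
        t_closed = survival_time_weibull(U1, U2, 0.0, gamma, lam, nu, M)
        f = lambda t: lam * t**nu * math.exp(gamma * (U1 + U2 * t)) + math.log(M)
        t_root = optimize.brentq(f, 1e-12, 100.0, xtol=1e-14)
        assert abs(t_closed - t_root) < 1e-8
        assert abs(t_closed - 2.405) < 5e-3

    def test_nu_one_reduces_to_exponential(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            U1, U2 = rng.normal(size=2)
            xb = rng.normal()
            gamma = rng.normal() * 0.5
            lam = rng.uniform(0.01, 2.0)
            M = rng.uniform(0.01, 0.99)
            te = survival_time_exponential(U1, U2, xb, gamma, lam, M)
            tw = survival_time_weibull(U1, U2, xb, gamma, lam, 1.0, M)
            assert te == tw or (np.isinf(te) and np.isinf(tw))

    def test_unreachable_event_is_infinite(self):
        # gamma*U2 < 0 bounds the cumulative hazard; tiny M is unreachable
        t = survival_time_exponential(0.0, -1.0, 0.0, 1.0, 0.1, 1e-8)
        assert np.isinf(t)

    @given(
        st.floats(-2, 2), st.floats(-1, 1), st.floats(-1, 1),
        st.floats(-0.8, 0.8), st.floats(0.01, 5.0), st.floats(0.3, 3.0),
        st.floats(0.01, 0.99),
    )
    @settings(max_examples=300, deadline=None)
    def test_defining_identity_weibull(self, U1, U2, xb, gamma, lam, nu, M):
        t = survival_time_weibull(U1, U2, xb, gamma, lam, nu, M)
        if np.isfinite(t):
            lhs = lam * t**nu * math.exp(xb + gamma * (U1 + U2 * t))
            target = -math.log(M)
            assert abs(lhs - target) <= 1e-10 * max(1.0, abs(target)) * 100

    def test_monotone_in_lambda_and_intercept(self):
        rng = np.random.default_rng(8)
        for _ in range(30):
            U1, U2 = rng.normal(size=2) * 0.3
            gamma, M = 0.4, rng.uniform(0.05, 0.95)
            lams = [0.01, 0.1, 1.0]
            ts = [survival_time_weibull(U1, U2, 0.0, gamma, l, 1.5, M)
                  for l in lams]
            assert ts[0] >= ts[1] >= ts[2]
            u1s = [-1.0, 0.0, 1.0]
            ts = [survival_time_weibull(u, U2, 0.0, gamma, 0.1, 1.5, M)
                  for u in u1s]
            assert ts[0] >= ts[1] >= ts[2]

    def test_invalid_m_rejected(self):
        with pytest.raises(ValueError):
            survival_time_exponential(0, 0, 0, 0, 1.0, 1.5)


class TestGenerateDataset:
    def test_deterministic_limit_no_noise(self):
        params = GenParams(
            sigma2=0.0,
            G=np.array([[1e-12, 0.0], [0.0, 1e-14]]),
            gamma=0.0, lam=1e-3, nu=1.0, n=20, seed=2,
        )
        panels, _, _ = generate_dataset(params)
        for p in panels:
            expect = 4.25 + 0.25 * p.times + params.beta_age_long * p.age
            np.testing.assert_allclose(p.values, expect, atol=1e-5)

    def test_gamma0_exponential_ks(self):
        # gamma = 0, nu = 1: S_i ~ Exponential(lam * e^{X'beta}) exactly
        params = GenParams(gamma=0.0, lam=1e-3, nu=1.0, n=5000, seed=9)
        _, _, truths = generate_dataset(params)
        rng = np.random.default_rng(9)
        # transform each S by its own CDF: should be uniform
        age, sex = simgen._draw_baseline(params, np.random.default_rng(9), 1)
        u = []
        for t in truths:
            # recover rate from the defining identity: lam*S*e^xb = -log M
            if np.isfinite(t.S):
                u.append(1 - t.M)  # M uniform implies F(S) = 1 - M
        ks = stats.kstest(u, "uniform")
        assert ks.pvalue > 0.01

    def test_observation_schedule_and_truncation(self, small_dataset):
        panels, survs, _ = small_dataset
        surv = {s.subject_id: s for s in survs}
        for p in panels:
            assert p.m <= 6
            assert p.times[0] == 0.0
            assert p.times[-1] <= surv[p.subject_id].time + 1e-12

    def test_seed_reproducibility(self, table1_params):
        a = generate_dataset(table1_params)
        b = generate_dataset(table1_params)
        for pa, pb in zip(a[0], b[0]):
            np.testing.assert_array_equal(pa.values, pb.values)
        for ta, tb in zip(a[2], b[2]):
            assert (ta.U1, ta.U2, ta.M, ta.S, ta.C) == (tb.U1, tb.U2, tb.M, tb.S, tb.C)


class TestCalibration:
    def test_tiny_lambda_censors_everything(self):
        params = GenParams(gamma=0.0, nu=1.5, n=10, seed=0)
        frac = simgen._censoring_fraction(
            params, 1e-10,
            self_draws(params, 2000, 0),
        )
        assert frac > 0.99

    def test_quadrature_oracle_gamma0(self):
        # no covariates, gamma = 0: P(censored) = E_C exp(-lam C^nu)
        params = GenParams(
            gamma=0.0, nu=1.5, alpha_age=0.0, alpha_sex=0.0, n=10, seed=0
        )
        lam = calibrate_lambda(params, 0.5, reps=20000, seed=4)
        exact = simgen.censoring_fraction_gamma0(params, lam)
        assert abs(exact - 0.5) < 0.03

    @pytest.mark.parametrize("target", [0.10, 0.50, 0.90])
    def test_calibration_hits_target(self, target):
        params = GenParams(gamma=0.5, nu=1.5, sigma2=0.1161, n=10, seed=0)
        lam = calibrate_lambda(params, target, reps=5000, seed=1)
        achieved = simgen._censoring_fraction(
            params, lam, self_draws(params, 20000, 99)
        )
        assert abs(achieved - target) < 0.02

    def test_unreachable_target_raises(self):
        params = GenParams(gamma=0.0, nu=1.5, n=10, seed=0)
        with pytest.raises(ValueError):
            calibrate_lambda(params, 1e-9, reps=500, seed=0,
                             lam_bounds=(1e-4, 1e-2))


def self_draws(params, reps, seed):
    rng = np.random.default_rng(seed)
    age, sex = simgen._draw_baseline(params, rng, reps)
    U = rng.multivariate_normal(params.mu, params.G, size=reps)
    M = rng.uniform(size=reps)
    C = rng.uniform(params.cens_low, params.cens_high, size=reps)
    return age, sex, U, M, C
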