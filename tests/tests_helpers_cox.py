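"""Shared brute-force partial-likelihood oracle for acceptance checks."""

import numpy as np

from trajsurv.coxtd import expand_lvcf, fit_cox_td, partial_loglik


def brute_force_logpl(table, beta):
    """Direct risk-set enumeration (Breslow) — independent of the engine."""
    import math

    df = table.data
    X = df[list(table.covariate_names)].to_numpy(dtype=float)
    eta = X @ np.asarray(beta)
    ll = 0.0
    ev = df[df["status"] == 1]
    for t in sorted(ev["stop"].unique()):
        dead = df.index[(df["status"] == 1) & (df["stop"] == t)]
        risk = df.index[(df["start"] < t) & (t <= df["stop"])]
        ll += eta[dead].sum() - len(dead) * math.log(np.exp(eta[risk]).sum())
    return ll


def check_partial_likelihood(panels, survival, tol=1e-10):
    table = expand_lvcf(panels, survival)
    fit = fit_cox_td(table)
    beta = [fit.coefficients[c] for c in table.covariate_names]
    direct = brute_force_logpl(table, beta)
    assert abs(fit.loglik - direct) < tol
    assert abs(partial_loglik(table, beta) - direct) < tol
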