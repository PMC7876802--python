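"""One-call comparison estimators of the link parameter gamma.

* TSA (two-step approach, ordinary regression calibration): fit the mixed
  model on all subjects, substitute predicted trajectories into a
  time-dependent Cox model broken at event times.  Stage-2 Wald inference
  only — first-stage uncertainty is deliberately not propagated.
* TDCM (time-dependent covariate model): the observed measurements enter
  the Cox model by last-value-carried-forward.

Joint-likelihood counterparts live in :mod:`trajsurv.jointml` (MLA) and
:mod:`trajsurv.bayesjoint` (BSJM); this module wraps all four behind a
common :class:`MethodResult`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from . import coxtd, lme

__all__ = ["MethodResult", "fit_tsa", "fit_tdcm", "fit_method"]

Z975 = 1.959963984540054


@dataclass
class MethodResult:
    method: str                      # TSA / TDCM / MLA / BSJM
    gamma_hat: float
    gamma_se: float
    alpha_age_hat: float
    alpha_age_se: float
    alpha_sex_hat: float
    alpha_sex_se: float
    converged: bool
    loglik: float = float("nan")
    ci95: tuple = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.ci95 is None:
            self.ci95 = (
                self.gamma_hat - Z975 * self.gamma_se,
                self.gamma_hat + Z975 * self.gamma_se,
            )


class StageError(RuntimeError):
    """Failure in a named stage of a multi-stage estimator."""

    def __init__(self, stage: str, original: Exception):
        super().__init__(f"stage '{stage}' failed: {original}")
        self.stage = stage
        self.original = original


def _from_cox(method: str, fit: coxtd.CoxFit, extra=None) -> MethodResult:
    return MethodResult(
        method=method,
        gamma_hat=fit.coefficients["value"],
        gamma_se=fit.se["value"],
        alpha_age_hat=fit.coefficients["age"],
        alpha_age_se=fit.se["age"],
        alpha_sex_hat=fit.coefficients["sex"],
        alpha_sex_se=fit.se["sex"],
        converged=fit.converged,
        loglik=fit.loglik,
        extra=extra or {},
    )


def fit_tsa(panels, survival, include_age: bool = True) -> MethodResult:
    """Two-step approach: LME on all subjects, then predicted-value Cox."""
    try:
        stage1 = lme.fit_lme(panels, include_age=include_age)
    except Exception as exc:  # noqa: BLE001 - re-raised with stage label
        raise StageError("lme", exc) from exc
    try:
        table = coxtd.expand_predicted(stage1, panels, survival)
        stage2 = coxtd.fit_cox_td(table)
    except Exception as exc:  # noqa: BLE001
        raise StageError("cox", exc) from exc
    res = _from_cox("TSA", stage2, extra={"lme": stage1})
    res.converged = res.converged and stage1.converged
    return res


def fit_tdcm(panels, survival) -> MethodResult:
    """Time-dependent covariate model: LVCF expansion, then Cox."""
    table = coxtd.expand_lvcf(panels, survival)
    return _from_cox("TDCM", coxtd.fit_cox_td(table))


def fit_method(method: str, panels, survival, **kwargs) -> MethodResult:
    """Dispatch by method name (tsa, tdcm, mla, bayes/bsjm)."""
    key = method.lower()
    if key == "tsa":
        return fit_tsa(panels, survival, **kwargs)
    if key == "tdcm":
        return fit_tdcm(panels, survival)
    if key == "mla":
        from .jointml import fit_joint_ml

        return fit_joint_ml(panels, survival, **kwargs).as_method_result()
    if key in ("bayes", "bsjm"):
        from .bayesjoint import run_mcmc

        return run_mcmc(panels, survival, **kwargs).as_method_result()
    raise ValueError(f"unknown method {method!r}")
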