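"""Counting-process Cox engine and the LVCF / predicted expansions."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from trajsurv import simgen
from trajsurv.core_data import CountingProcessTable, LongPanel, SurvivalRecord
from trajsurv.coxtd import (
    expand_lvcf,
    expand_predicted,
    fit_cox_td,
    partial_loglik,
)
from trajsurv.lme import fit_lme, predict_trajectory


def simple_table(rows, covs=("value",)):
    cols = ["id", "start", "stop", "status", *covs]
    df = pd.DataFrame(rows, columns=cols)
    for c in ("age", "sex"):
        if c not in df.columns and c in CountingProcessTable(
            pd.DataFrame(columns=cols + ["age", "sex"]), covs
        ).covariate_names:
            df[c] = 0.0
    return CountingProcessTable(df, covs)


def brute_force_logpl(table, beta):
    """Direct risk-set enumeration of the Breslow log partial likelihood."""
    df = table.data
    X = df[list(table.covariate_names)].to_numpy(dtype=float)
    eta = X @ np.asarray(beta)
    ll = 0.0
    ev = df[df["status"] == 1]
    for t in sorted(ev["stop"].unique()):
        dead = df.index[(df["status"] == 1) & (df["stop"] == t)]
        risk = df.index[(df["start"] < t) & (t <= df["stop"])]
        d = len(dead)
        ll += eta[dead].sum() - d * math.log(np.exp(eta[risk]).sum())
    return ll


class TestFitCox:
    def test_symmetric_tie_gives_zero(self):
        tab = simple_table([
            ("a", 0.0, 1.0, 1, 1.0),
            ("b", 0.0, 1.0, 1, -1.0),
        ])
        fit = fit_cox_td(tab)
        assert abs(fit.coefficients["value"]) < 1e-10

    def test_three_subject_known_value(self):
        tab = simple_table([
            ("a", 0.0, 1.0, 1, 1.0),
            ("b", 0.0, 2.0, 1, 2.0),
            ("c", 0.0, 3.0, 0, 0.0),
        ])
        fit = fit_cox_td(tab)
        # grid maximization of the 2-term partial likelihood gives 0.66901
        assert abs(fit.coefficients["value"] - 0.66901347) < 1e-6

    def test_matches_lifelines_on_time_constant_covariates(self, small_dataset):
        from lifelines import CoxPHFitter

        panels, survs, _ = small_dataset
        rows = [
            (p.subject_id, 0.0, s.time, s.event, p.values[0], p.age, p.sex)
            for p, s in zip(panels, survs)
        ]
        tab = CountingProcessTable(
            pd.DataFrame(rows, columns=["id", "start", "stop", "status",
                                        "value", "age", "sex"])
        )
        fit = fit_cox_td(tab)
        df = pd.DataFrame(rows, columns=["id", "start", "stop", "status",
                                         "value", "age", "sex"])
        cph = CoxPHFitter().fit(
            df[["stop", "status", "value", "age", "sex"]],
            duration_col="stop", event_col="status",
        )
        for name in ("value", "age", "sex"):
            assert abs(fit.coefficients[name] - cph.params_[name]) < 1e-5
            assert abs(fit.se[name] - cph.standard_errors_[name]) < 1e-5

    def test_loglik_matches_brute_force(self, small_dataset):
        panels, survs, _ = small_dataset
        tab = expand_lvcf(panels[:25], survs[:25])
        fit = fit_cox_td(tab)
        beta = [fit.coefficients[c] for c in tab.covariate_names]
        assert abs(fit.loglik - brute_force_logpl(tab, beta)) < 1e-10
        assert abs(partial_loglik(tab, beta) - fit.loglik) < 1e-10

    def test_score_zero_at_optimum(self, small_dataset):
        panels, survs, _ = small_dataset
        tab = expand_lvcf(panels, survs)
        fit = fit_cox_td(tab)
        assert fit.converged
        beta = np.array([fit.coefficients[c] for c in tab.covariate_names])
        h = 1e-6
        for i in range(3):
            e = np.zeros(3)
            e[i] = h
            g = (partial_loglik(tab, beta + e) - partial_loglik(tab, beta - e)) / (2 * h)
            assert abs(g) < 1e-4

    def test_shift_invariance(self, small_dataset):
        panels, survs, _ = small_dataset
        tab = expand_lvcf(panels, survs)
        shifted = CountingProcessTable(
            tab.data.assign(value=tab.data["value"] + 10.0),
            tab.covariate_names,
        )
        f1, f2 = fit_cox_td(tab), fit_cox_td(shifted)
        assert abs(f1.coefficients["value"] - f2.coefficients["value"]) < 1e-8

    def test_zero_events_raises(self):
        tab = simple_table([("a", 0.0, 1.0, 0, 1.0)])
        with pytest.raises(ValueError, match="no events"):
            fit_cox_td(tab)

    def test_monotone_likelihood_flagged(self):
        # perfect separation: larger covariate always fails first
        rows = [(f"s{i}", 0.0, float(i + 1), 1, float(-i)) for i in range(6)]
        tab = simple_table(rows)
        with pytest.warns(RuntimeWarning):
            fit = fit_cox_td(tab, max_iter=25)
        assert not fit.converged

    def test_efron_differs_from_breslow_under_ties(self):
        tab = simple_table([
            ("a", 0.0, 1.0, 1, 1.0),
            ("b", 0.0, 1.0, 1, 0.5),
            ("c", 0.0, 2.0, 1, 0.0),
            ("d", 0.0, 3.0, 0, 0.2),
        ])
        fb = fit_cox_td(tab, ties="breslow")
        fe = fit_cox_td(tab, ties="efron")
        assert fb.coefficients["value"] != fe.coefficients["value"]


class TestExpandLvcf:
    def test_basic_expansion(self):
        panels = [LongPanel("a", [0.0, 4.0], [1.5, 2.5], 50.0, 0)]
        survs = [SurvivalRecord("a", 7.0, 1)]
        tab = expand_lvcf(panels, survs)
        df = tab.data
        assert list(df["start"]) == [0.0, 4.0]
        assert list(df["stop"]) == [4.0, 7.0]
        assert list(df["value"]) == [1.5, 2.5]
        assert list(df["status"]) == [0, 1]

    def test_measurement_at_event_time_unused(self):
        panels = [LongPanel("a", [0.0, 4.0, 7.0], [1.0, 2.0, 9.0], 50.0, 0)]
        survs = [SurvivalRecord("a", 7.0, 1)]
        tab = expand_lvcf(panels, survs)
        # strict carry-forward: the t=7 measurement never enters
        assert 9.0 not in set(tab.data["value"])
        assert list(tab.data["stop"]) == [4.0, 7.0]

    def test_exposure_conserved(self, small_dataset):
        panels, survs, _ = small_dataset
        tab = expand_lvcf(panels, survs)
        exposure = tab.data.groupby("id", sort=True)\
            .apply(lambda g: (g["stop"] - g["start"]).sum(), include_groups=False)
        times = {s.subject_id: s.time for s in survs}
        for sid, exp_t in exposure.items():
            assert abs(exp_t - times[sid]) < 1e-12

    def test_missing_baseline_raises(self):
        panels = [LongPanel("a", [1.0, 4.0], [1.0, 2.0], 50.0, 0)]
        survs = [SurvivalRecord("a", 7.0, 1)]
        with pytest.raises(ValueError, match="baseline"):
            expand_lvcf(panels, survs)


class TestExpandPredicted:
    def test_at_risk_values_are_event_time_predictions(self, small_dataset):
        panels, survs, _ = small_dataset
        panels, survs = panels[:30], survs[:30]
        fit = fit_lme(panels)
        tab = expand_predicted(fit, panels, survs)
        tab.validate()
        ev_times = sorted({s.time for s in survs if s.event})
        df = tab.data
        for t in ev_times[:10]:
            risk = df[(df["start"] < t) & (t <= df["stop"])]
            for _, row in risk.iterrows():
                if row["stop"] == t:
                    expect = predict_trajectory(fit, row["id"], t)
                    assert abs(row["value"] - expect) < 1e-12

    def test_partial_likelihood_matches_direct_formula(self, small_dataset):
        panels, survs, _ = small_dataset
        panels, survs = panels[:20], survs[:20]
        fit = fit_lme(panels)
        tab = expand_predicted(fit, panels, survs)
        beta = np.array([0.3, 0.02, -0.4])
        # direct evaluation: for each event, predicted values at that time
        tmap = {s.subject_id: s for s in survs}
        ll = 0.0
        for s in sorted(survs, key=lambda r: r.time):
            if not s.event:
                continue
            t = s.time
            num = None
            den = 0.0
            for p in panels:
                if tmap[p.subject_id].time >= t:
                    eta = (beta[0] * predict_trajectory(fit, p.subject_id, t)
                           + beta[1] * p.age + beta[2] * p.sex)
                    den += math.exp(eta)
                    if p.subject_id == s.subject_id:
                        num = eta
            ll += num - math.log(den)
        assert abs(partial_loglik(tab, beta) - ll) < 1e-10

    def test_row_order_and_relabeling_invariance(self, small_dataset):
        panels, survs, _ = small_dataset
        panels, survs = panels[:40], survs[:40]
        fit = fit_lme(panels)
        t1 = expand_predicted(fit, panels, survs)
        perm = list(reversed(range(len(panels))))
        t2 = expand_predicted(fit, [panels[i] for i in perm],
                              [survs[i] for i in perm])
        f1, f2 = fit_cox_td(t1), fit_cox_td(t2)
        for name in ("value", "age", "sex"):
            assert abs(f1.coefficients[name] - f2.coefficients[name]) < 1e-10
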