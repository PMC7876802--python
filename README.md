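# trajsurv

Tools for studying how a longitudinally measured biomarker drives a
time-to-event outcome, built around the comparison of four estimators of
the *link parameter* — the log hazard ratio per unit of the current,
error-free trajectory value.

The motivating setting is a Framingham-style cohort: a log-scale lipid
measure recorded at roughly 4-yearly exams, baseline age and sex, and
right-censored follow-up for myocardial infarction.  Each subject carries
a latent linear trajectory

```
Y*_i(t) = U_i1 + U_i2 t + beta_age * Age_i,      (U_i1, U_i2) ~ MVN(mu, G)
Y_ij    = Y*_i(t_ij) + eps_ij,                   eps_ij ~ N(0, sigma^2)
```

and a proportional-hazards event model

```
h_i(t) = h_0(t) exp{ gamma * Y*_i(t) + alpha_1 Age_i + alpha_2 Sex_i }.
```

Because `Y*` is observed only with error and only at exam times, the
choice of estimator for `gamma` matters:

| method | idea |
|--------|------|
| TDCM | time-dependent Cox on the raw measurements, last value carried forward |
| TSA  | two-step regression calibration: mixed model first, then Cox on the predicted trajectory at event times |
| MLA  | maximum-likelihood Weibull shared-parameter joint model (Gauss–Hermite over the random effects, hybrid ECM → quasi-Newton) |
| BSJM | Bayesian joint model with a constant baseline hazard, Metropolis-within-Gibbs |

The package also contains the piece that makes the comparison possible at
scale: a closed-form simulator for event times with a *time-varying*
linear predictor.  The cumulative hazard
`H(t) = lambda t^nu exp{X'beta + gamma (U1 + U2 t)}` is inverted
analytically with the principal branch of the Lambert W function, so
millions of survival times can be drawn without root-finding, for both
Exponential (`nu = 1`) and Weibull baselines.  A second generation scheme
inverts the exact integrated hazard of the joint fitting model
numerically, for self-consistent benchmarking.

## Worked example

```python
import trajsurv as ts

# 200 subjects, 6 exams, link gamma = 0.5, ~10% censoring
params = ts.GenParams(gamma=0.5, lam=4.2e-6, nu=1.5, n=200, seed=6)
panels, survival, truth = ts.generate_dataset(params)

tsa  = ts.fit_tsa(panels, survival)
tdcm = ts.fit_tdcm(panels, survival)
print(f"TSA  gamma = {tsa.gamma_hat:.3f} (se {tsa.gamma_se:.3f})")
print(f"TDCM gamma = {tdcm.gamma_hat:.3f} (se {tdcm.gamma_se:.3f})")
```

prints

```
TSA  gamma = 0.497 (se 0.188)
TDCM gamma = 0.265 (se 0.141)
```

The two-step estimate sits near the generating value 0.5 while the
carried-forward raw measurements attenuate the estimate toward zero —
the central phenomenon the toolkit quantifies.  The same comparisons run
from the shell:

```bash
trajsurv simulate --distribution weibull --n 200 --gamma 0.5 \
        --censoring 0.10 --seed 6 --out-prefix sim
trajsurv fit --method tsa  --panel sim_panel.csv --survival sim_survival.csv
trajsurv fit --method mla  --panel sim_panel.csv --survival sim_survival.csv
trajsurv study --config grid.yaml --out-dir results/
```

Real cohort data enter through the same two CSVs (long-format panel
`id,time,y,age,sex`; survival `id,time,event`).

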