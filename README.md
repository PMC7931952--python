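# latentshift

Latent-time nonlinear mixed-effects disease progression modeling for
longitudinal cognitive scores.

In slowly progressing dementias such as Alzheimer disease, each study
participant is observed over a few years of a decline that unfolds over
one to two decades, and participants enter the study at unknown points of
that decline. `latentshift` aligns the observed short trajectories onto a
common disease timeline by estimating a latent time shift per subject,
separating three things that a single cognitive assessment confounds:
**disease stage**, **rate of decline**, and **pre-disease level of
cognition**. It is aimed at biostatisticians and researchers working with
longitudinal cognitive or clinical-scale data (e.g., ADAS-Cog) in
observational cohorts or trials.

## Model

The score of subject *i* at study time *t<sub>ij</sub>* (months since
baseline) is modeled as

```
y_ij = l · exp((t_ij + s_i + X_s,i β_s) / exp(g)) + v
       + x_i,0 + x_i,BM(t_ij) + ε_ij
```

* `l`, `g`, `v` — shape of the mean decline curve: scale, log time-scale
  and left asymptote (average pre-disease score);
* `X_s,i β_s` — fixed stage offsets (months): dummy coding of the
  baseline group (cognitively normal = reference, with shift fixed at 0
  for identifiability) plus optional stage covariates such as baseline
  biomarkers;
* `s_i ~ N(0, τ²)` — random time shift: the subject's displacement along
  the disease timeline;
* `x_i,0` — random starting level, correlated with the shift through
  `Cov(s_i, x_i,0) = ρ σ₀²`;
* `x_i,BM` — Brownian-motion deviation with covariance
  `σ_BM² · min(t, t′)`, indexed by study time;
* `ε_ij ~ N(0, σ²)` — measurement noise.

Covariate effects can additionally act on the rate (`g`) and level (`v`)
channels as regression terms. Estimation is maximum likelihood: a
penalized nonlinear least-squares / linear mixed-effects warm-up followed
by direct minimization of the Laplace approximate marginal likelihood,
with an exact Gauss–Hermite quadrature likelihood available as a
diagnostic. Subject stages are predicted as posterior modes
(empirical Bayes); covariate placement is chosen by forward selection
(continue while AIC improves, choose the final model by BIC, using
AIC = −2LL + 2·df and BIC = −2LL + ln(N)·df with N the observation
count).

## Worked example

```python
import numpy as np
from latentshift import (ModelSpec, build_designs, fit_ml,
                         predict_random_effects)
from latentshift.simulate import SimulationConfig, simulate_dataset

cfg = SimulationConfig(n_subjects=300, seed=1)
dataset, truth = simulate_dataset(cfg)
fit = fit_ml(dataset, ModelSpec())
p = fit.params
print(f"df={fit.df}  -2LL={fit.neg2ll:.2f}  AIC={fit.aic:.2f}  BIC={fit.bic:.2f}")
print("group stage offsets (months):",
      np.round(p.beta_s, 1), " (generating values 29/42/88/136)")
print(f"curve: l={p.l:.2f}  exp(g)={np.exp(p.g):.1f} months  v={p.v:.2f}")
designs = build_designs(dataset, ModelSpec())
s_hat = np.array([predict_random_effects(s, p, designs.row(i)).s_hat
                  for i, s in enumerate(dataset.subjects)])
corr = np.corrcoef(s_hat, truth["subjects"]["s_true"])[0, 1]
print(f"staging correlation with truth: {corr:.2f}")
```

prints

```
df=12  -2LL=7619.77  AIC=7643.77  BIC=7706.68
group stage offsets (months): [ 39.   53.6  93.7 144.3]  (generating values 29/42/88/136)
curve: l=0.98  exp(g)=46.4 months  v=8.55
staging correlation with truth: 0.83
```

The basic five-group model has 12 free parameters (three curve
parameters, four group stage offsets, five variance components). The
fitted stage offsets place the symptomatic groups roughly 3–12 years
later on the disease timeline than the cognitively normal group, and the
posterior-mode shifts recover each subject's simulated displacement with
correlation 0.83 at this cohort size.

A command-line interface mirrors the library:

```
latentshift simulate --out cohort.csv --seed 7 --n-subjects 500
latentshift fit      --data cohort.csv --out fit.json
latentshift predict  --fit fit.json --data cohort.csv --out staging.csv
latentshift select   --data cohort.csv --pool age,sex,education --out trace.csv
latentshift validate timescale --data long.csv --outcome cdr --out table.csv
```

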