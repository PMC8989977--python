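# protect-scm

Proxy-based individual treatment effect estimation under unobserved
confounding, for observational cancer cohorts with right-censored survival
outcomes.

## The problem

In observational cancer data the most effective treatment is usually also
the most intensive one, and physicians steer fitter patients toward it.
The physician's overall impression of a patient's *fitness* is not recorded
anywhere, so the central confounder of the treatment–survival relationship
is unobserved and ordinary covariate adjustment (multivariable Cox,
propensity weighting) cannot close the back door. What *is* recorded are
proxy variables — performance status, renal function — that are caused by
fitness but have no causal effect of their own on the treatment decision or
survival. A second latent, the biological aggressiveness of the tumor
(*behavior*), is seen only through biomarkers: weight loss, histology, TNM
substage.

This package implements the resulting Bayesian structural causal model for
stage III non-small cell lung cancer (concurrent vs sequential
chemoradiation), and everything needed to validate it end to end on
synthetic cohorts with known ground truth.

## The model

Latents (unit scale for identifiability):

    U_b ~ N(0, 1)                    tumor behavior
    U_f ~ N(alpha * age_z, 1)        patient fitness

Proxies (logit links; fitness proxies adverse-coded with nonnegative
loadings, which anchors the latent orientation):

    logit P(PS >= 1)        = kappa_0 - kappa_1 U_f      kappa_1 >= 0
    logit P(eGFR < 60)      = lambda_0 - lambda_1 U_f    lambda_1 >= 0
    logit P(weight loss)    = mu_0 + mu_1 U_b            mu_1 >= 0
    logit P(stage IIIB/C)   = nu_0 + nu_1 U_b            nu_1 >= 0
    histology               ~ categorical-logit in U_b (adeno reference)

Treatment decision and outcome:

    logit P(A = 1)  = tau_0 + tau_f U_f + tau' x
    h(t | A, x, U)  = k t^{k-1} exp(eta),
    eta = beta_0 + beta_A A + beta_f U_f + beta_b U_b + beta' x
          + A * (gamma' x_int + gamma_f U_f)

The individual treatment effect (ITE) for patient i is the log hazard
ratio of concurrent versus sequential treatment given the pre-treatment
variables, with the unobserved fitness replaced by its posterior given the
proxies (back-door adjustment over the reconstructed confounder):

    Delta_i = beta_A + gamma' x_int,i + gamma_f E[U_f | x_i]

and the average treatment effect (ATE) is the cohort mean of the Delta_i
per posterior draw, reported as a hazard ratio with a 95% credible
interval.

The posterior is sampled with an in-package No-U-Turn sampler on the
*collapsed* model: the per-patient latents are integrated out with
Gauss–Hermite quadrature and the ~35 structural parameters are sampled
with analytically differentiated gradients (see `docs/methods.md`).

## Worked example

```python
import numpy as np
from protect import (build_nsclc_dag, generate_cohort, nsclc_like_params,
                     fit, MCMCConfig, diagnostics, effects, baselines)

params = nsclc_like_params()                    # nsclc-like generating scenario
cohort, truth = generate_cohort(params, 504, seed=7, switch=(-0.5, 1.0))

draws = fit(build_nsclc_dag(), cohort,
            mcmc=MCMCConfig.reduced(seed=1, n_chains=4, n_warmup=1200, n_samples=1000))
print(diagnostics(draws))

ate = effects.ate(draws, cohort)
print(f"PROTECT ATE hazard ratio: {ate.hr:.2f} (95% CrI {ate.ci_low:.2f}-{ate.ci_high:.2f})")
print(f"true ATE hazard ratio:    {np.exp(truth.true_ate_loghr):.2f}")

covs = ["age_z", "histology", "weight_loss", "stage_iiib_c", "ps_geq1", "egfr_lt60"]
print(f"unadjusted Cox HR:        {baselines.cox_fit(cohort, []).hr:.2f}")
print(f"adjusted Cox HR:          {baselines.cox_fit(cohort, covs).hr:.2f}")
print(f"switch AUC (concurrent):  {baselines.switch_check(draws, cohort):.2f}")
```

Output of this exact script:

```
max split r-hat: 1.0279
divergences: 0 (0.00%)
unimodal: outcome_treatment=True, outcome_fitness=True, treatment_fitness=True, interaction_fitness=True, weibull_shape=True
overall pass: False
PROTECT ATE hazard ratio: 2.43 (95% CrI 0.97-7.02)
true ATE hazard ratio:    1.11
unadjusted Cox HR:        0.66
adjusted Cox HR:          0.80
switch AUC (concurrent):  0.59
```

What the numbers mean: the simulated cohort has essentially no average
treatment benefit (true HR 1.11), but fitter patients were preferentially
given concurrent treatment, so both conventional estimators point firmly
toward benefit (HR 0.66 unadjusted, 0.80 adjusted) — residual confounding
that no observed-covariate adjustment can remove. The structural model's
credible interval is wide at this cohort size but covers the truth, and
patients with lower reconstructed fitness were more likely to switch away
from their planned treatment (AUC 0.59), an independent check that the
latent means what it should. The diagnostics line flags that this
reduced sampler budget has not yet reached the strict r-hat < 1.01 bar;
the full-scale protocol is `MCMCConfig()` (16 chains, 7500 draws after
2500 warm-up).

A thin CLI wraps the same pipeline:

```bash
protect simulate --n 504 --seed 7 --out cohort.csv --truth-out truth.json
protect fit --input cohort.csv --reduced --seed 1 --out posterior.npz
protect report --input cohort.csv --seed 1 --out comparison.csv
```

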