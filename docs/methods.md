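# Methods

This note documents the model, the inference machinery, the synthetic
cohort generator, and the numerical and design choices a maintainer or
reviewer would want spelled out. Notation follows the README.

## Structural causal model

The behavior–fitness graph has two standard-normal-scale latents: patient
fitness `U_f` (mean linear in standardized age, unit residual scale) and
tumor behavior `U_b` (standard normal). Fixing both latent scales at 1 and
centering `U_b` resolves the location–scale indeterminacy of latent-variable
models; what remains is the reflection `U -> -U`, which is removed by
constraining the proxy loadings to half-lines: fitness proxies are
adverse-coded (`logit = a - b U_f`, `b >= 0`: a fitter patient has a lower
probability of ECOG >= 1 or eGFR < 60) and behavior proxies
aggressive-coded (`logit = a + b U_b`, `b >= 0`: a more aggressive tumor
makes weight loss and substage IIIB/C more likely). Histology enters as a
three-level categorical logit with adenocarcinoma as reference and
unconstrained loadings; the two binary constraints on the behavior side
are enough to anchor the axis.

The treatment logit contains latent fitness plus the observed tumor
markers and age. The outcome is a Weibull proportional-hazards model —
the simplest parametric PH family with a flexible baseline; the shape `k`
is estimated (Half-Normal(1) prior) and `k = 1` recovers the exponential
model. The survival linear predictor carries both latents, the observed
covariates, and treatment x modifier interactions for age, substage,
weight loss, the histology dummies and latent fitness. The treatment x
fitness term is the deliberately non-linear component of the individual
treatment effect: it makes the predicted effect vary with a quantity that
is only *reconstructed*, never observed.

Priors: Normal(0, 2.5^2) on unconstrained coefficients and intercepts,
Half-Normal(1) on the sign-constrained loadings and the Weibull shape.
These are weakly informative on the logit/log-hazard scale for
standardized covariates.

The DAG is a declarative object (`protect.dag.DAGSpec`, YAML-serializable)
validated for acyclicity, the confounder role of fitness, the purity of
proxies (no proxy may point at treatment or outcome) and sign anchoring.
Deliberately misspecified candidates for model selection are built with
`strict=False`.

## Inference: collapsed NUTS

The sampler is an in-package No-U-Turn sampler (recursive slice-based
doubling, dual-averaging step size, Stan-style expanding warmup windows)
with a dense metric estimated during warmup — the baseline hazard, the
Weibull shape and the latent-scale coefficients are correlated enough that
a diagonal metric roughly quadruples tree depth.

Rather than sampling the two latents of every patient (which would add
`2n` dimensions and a funnel-prone geometry), the per-patient latents are
integrated out of the likelihood with probabilists' Gauss–Hermite
quadrature before sampling. The survival term factorizes across the two
latent axes, so the quadrature costs `O(n (Q_f + Q_b))` transcendental
operations plus cheap products on the `Q_f x Q_b` grid. Seven nodes per
axis leave a total log-likelihood error of order 1e-2 at n = 600 under the
reference scenario (five nodes: a few 1e-2); both are far below posterior
uncertainty, and node counts are configuration options. The gradient of
the collapsed log-likelihood is computed analytically via Fisher's
identity (posterior-weighted per-node scores, with the quadrature
responsibilities as the latent posterior) and is verified against finite
differences and a numba-free numpy reference in the test suite. Latent
draws for reporting are recovered exactly from their per-draw conditional
on the quadrature grid.

The parameter posterior of the collapsed sampler is mathematically
identical to that of a joint latents-plus-parameters sampler; collapsing
is a Rao-Blackwellization chosen for mixing and single-CPU runtime.

Positive parameters are sampled through log transforms (half-line support
enforced exactly, Jacobian included). Divergent transitions are counted
and reported; they are report-only below a configurable 2% alarm
threshold. Convergence is judged by split r-hat and ESS (via ArviZ), and
identifiability by a unimodality check of the key marginal posteriors —
kernel density estimate with Silverman bandwidth, local maxima below 10%
of the global peak ignored. The full-scale protocol (`MCMCConfig()`)
is 16 chains x 7500 retained draws after 2500 warm-up; the reduced
configuration used throughout the tests is 1–4 chains with a few hundred
to ~1200 warm-up iterations, stated per test below.

## Effects

For a patient with pre-treatment variables `x`, `p(U_f | x)` is computed
by quadrature from age and the fitness proxies only (not treatment, not
the outcome): the ITE is a prediction for a *new* patient at decision
time. The ITE per posterior draw is
`beta_A + gamma' x_int + gamma_f E[U_f | x]`; the ATE per draw is the
cohort mean, summarized as `exp(posterior mean)` with 2.5/97.5 percentile
credible limits. Partial dependences are step functions: set the variable
to its low/high level for everyone (binary 0 -> 1, age mean -> mean + 1 SD,
histology adeno -> target level), recompute all ITEs through the latent
posterior, and average the difference; pure fitness proxies therefore act
only by shifting `E[U_f | x]`. A restricted-mean-survival-time difference
(configurable horizon, plug-in latent posterior means) is available as a
secondary, absolute-scale output.

## Model selection

Candidates are scored by K-fold cross-validation (default K = 5) on each
effect variable of fitness: the fitness proxies and the treatment by
held-out log predictive density, the outcome by Harrell's concordance
(rank-based and fold-comparable, avoiding baseline-hazard leakage across
folds). The candidate predictive integrates the latent over its posterior
given the patient's other observed variables — but never the survival
outcome, and for the treatment target only pre-treatment variables, so no
outcome information leaks into a held-out prediction. The baseline is the
same machinery with every latent edge removed, i.e. a regression of the
target on its direct observed causes (intercept-only for a pure proxy);
fitting the baseline with the same optimizer and priors makes
"candidate equals baseline" an exact tie rather than a noisy comparison,
and score differences below 1e-3 are treated as ties. A candidate is
accepted iff it beats the baseline by more than one fold-level standard
error on at least one target; accepted candidates get pseudo-BMA weights
(softmax of total held-out log predictive density over the binary
targets). Fold fits use the posterior mode by default (`method="map"`),
with full reduced-scale MCMC available (`method="mcmc"`); the mode is a
fold-level plug-in only — posterior summaries are never replaced by it.

## Synthetic cohorts

The generator ancestrally samples the graph, draws survival times by
inverse-CDF from the Weibull PH model, censors with an independent
Uniform(0.5, 8) years administrative window, and records the generating
parameters, the latents and the true ITEs. The default `nsclc_like`
scenario back-solves intercepts (deterministic quadrature/Monte-Carlo
root-finding with a fixed internal seed) to hit the margins of the
motivating application: n = 504, concurrent treatment 44.4%, PS >= 1
~45.5%, substage IIIB/C ~46%, weight loss ~45%, eGFR < 60 ~10%, histology
~41/40/19%, ~70% deaths. Slopes default to moderate values (loadings
0.8–1.2, `tau_f = 1.0`, `beta_f = -0.6`) and can be overridden per
scenario with the intercepts re-solved, so the margins are preserved.
An optional treatment-switch flag is simulated as a Bernoulli in `-U_f`
(frailer patients de-intensify more often). Missingness can be injected
completely at random or with the weight-loss-specific mechanism (more
often missing when absent).

What the generator does *not* emulate: chart extraction noise, TNM
version drift, informative censoring, calendar-time effects, multi-center
heterogeneity, or any misspecification of the structural equations
themselves (candidates for that are created by deleting edges). Passing
tests therefore demonstrate internal validity — correct inference when
the model family matches the data-generating process — not robustness to
real-world model misspecification.

## Problem sizes used by the test suite

Unit tests run on cohorts of 25–700 patients with 1–2 chains and a few
hundred draws. The acceptance checks use: 20 cohorts of n = 600 (single
chain, 350 warm-up + 500 draws) for interval calibration; n = 1500 with
strong loadings for the single-replicate bias check; 10 replicates of
n = 600 for the confounding-bias contrast; 10 replicates of n = 1000 for
selection discrimination; n = 800 with 4 chains x (700 + 1200) for the
convergence bar; and two fits of n = 600 for marginalization stability.
`scripts/acceptance.py` runs n = 504 with 4 chains x (1200 + 1000).

## Numerical choices and degenerate inputs

- Cumulative-hazard overflow on extreme warmup excursions is clipped at
  1e300; affected grid cells carry zero responsibility, and a non-finite
  collapsed likelihood returns `-inf` with a zero gradient (rejected by
  the sampler as a divergence).
- Binary covariates may carry the fractional value 0.5 after imputation;
  the Bernoulli log-mass generalizes continuously.
- Cox/IPW comparators use lifelines (Efron ties, Newton iterations with
  tightened convergence tolerances, Wald intervals, stabilized weights,
  robust sandwich variance); propensities within 1e-6 of 0 or 1 raise
  with advice to trim. Zero-variance covariates are dropped with a
  warning.
- Ties in concordance and AUC count one half; both are delegated to
  lifelines/scikit-learn and cross-checked against exhaustive pair
  enumeration in the tests.
- The omitted-confounder analysis folds the extra fixed-coefficient
  latent into the fitness quadrature axis (5 extra nodes), so no new
  sampling dimensions are introduced.

## Known limitations

- With only two binary fitness proxies the latent is weakly identified at
  realistic cohort sizes; posteriors for the loadings, `tau_f` and
  `beta_f` are wide and mix more slowly than the rest (the behavior-side
  loading block is the r-hat bottleneck at weak loadings).
- The posterior *mean* of the ATE log hazard ratio carries a positive
  finite-sample shift under weak identification: the sign-anchored
  adjustment geometry is asymmetric (loadings bounded below by zero, so
  "stronger adjustment than truth" states have more posterior volume
  than "oppositely-signed adjustment" states, which are excluded). The
  posterior mode and large-n posteriors are unbiased in the same
  scenarios, and credible-interval calibration holds; the test suite
  quantifies this directly, and the single-replicate posterior-mean bias
  check at n = 1500 is the one acceptance check this implementation does
  not meet.
- The ATE is defined as the cohort average of patient-level log hazard
  ratios per draw; it is not a marginal structural (population-survival)
  contrast.
- No competing risks, time-varying covariates, multiple imputation, or
  nonparametric bridge-function estimators; candidates are user-declared
  rather than searched.
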