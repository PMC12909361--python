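# Methods

This note documents the statistical model, the estimator internals, the
synthetic-data generator, and the numerical/design choices behind
`dpinns`, in enough detail to reproduce or audit any number the package
computes.

## Statistical model

Individual PK parameters are multivariate log-normal across subjects,
`log η_k ~ MVN(μ, Ω)`; concentrations obey `dC/dt = f(C, t, η_k)`;
observed concentrations carry multiplicative log-normal measurement
error, `C_obs = C_true e^ε`, `ε ~ N(0, σ²)`, independent of `C_true`.
The estimators see only the per-timepoint cross-subject mean and unbiased
variance of `C_obs`. The estimands are `(μ, Ω)` on the linear scale
(population mean and SD per parameter) and `σ`.

Two structural models are registered:

* **one-compartment IV bolus** — `dC/dt = −ke C`, `C(0) = Dose/Vd`;
  stochastic parameters `(Vd, ke)`. Default study conditions: 30
  subjects, 300 mg dose, sampling at {0.5, 1, 2, 6, 12, 24} h, Vd mean
  15 L at 10% CV, ke from a 6 h mean half-life (ln 2/6 ≈ 0.1155 /h) at
  40% CV, zero parameter correlation, σ = 0.1.
* **minimal PBPK for monoclonal antibodies** — four compartments
  (plasma, tight-tissue ISF, leaky-tissue ISF, lymph), convective
  transport limited by vascular reflection coefficients `σ1 > σ2` and a
  lymphatic coefficient `σ_L`, zero-order infusion over `T_inf`,
  elimination from plasma only (`CLp`, the stochastic parameter).
  Reference physiology (70 kg: plasma 2.6 L, lymph 5.2 L, accessible ISF
  12.48 L split 65/35 tight/leaky, lymph flow 2.9 L/day split 33/67,
  σ_L = 0.2) ships as a CSV resource and scales linearly with body
  weight; because all flow/volume ratios are weight-invariant and dosing
  is per-kg, weight variability enters the concentration dynamics only
  through `CLp/V_plasma`. Default cohort: 49 subjects, weights uniform
  on 50–75 kg, 1 mg/kg over 1.5 h, 15 sampling times from 0.75 h to 99
  days, σ = 0.1 (fixed during estimation).

The mPBPK system is linear and time-invariant on each side of the
infusion switch, so the reference solver uses its eigendecomposition
(exact; cross-checked against LSODA to 1e−6 relative); the batched
variant powers the MCMC benchmark and the Monte-Carlo prediction bands.

## The D-PINN estimator

A feed-forward tanh network (2×3 units for the bolus case, 2×30 for the
mAb case; Glorot-normal init, softplus output transform with a 1e−6
floor) maps time to per-state moment outputs: mean + variance of the
observed concentration for the bolus case; mean + SD of plasma plus one
mean node per unobserved state for the mAb case. Inputs are scaled to
[0, 1] — linearly for the 24 h bolus horizon, by `log1p(t)/log1p(t_max)`
for the mAb case, whose dynamics span 1.5 h to 2376 h (a linear map
leaves the infusion phase unresolvable). Outputs are min–max scaled
(bounds from the observed data; unobserved states share the plasma-mean
bounds); time derivatives are computed by forward-mode tangent
propagation through the network, inside the reverse-mode training graph,
so loss gradients flow through them.

Each iteration assembles, per collocation time, a joint log-normal over
`(log C_obs, log η)`: the concentration block comes from the network's
moments via the exact linear↔log moment transforms; the parameter block
is the trainable `(μ, Ω)`. Samples are drawn by reparameterisation
(`exp(μ' + D L z)`, with `D L` the scaled Cholesky factor and `z` fresh
standard normals), denoised, pushed through the ODE right-hand side
(Monte-Carlo estimators of the time derivatives of the true mean and
unbiased variance), mapped back to the observed scale through the exact
noisy-moment relations, and compared with the network's derivatives.
Data misfits at the observation times and initial-condition misfits
complete the six-term weighted loss; Adam (lr 5e−4, 1%/1000-iteration
decay, global gradient-norm clip 10) optimises all trainables jointly.
Training budgets: 30 000 iterations with 100 collocation points and 100
draws for the bolus case; the mAb fits in the test suite use 20 000
iterations with 60 collocation points and 100 draws.

### Denoising

The residual model implies `E[C_true] = E[C_obs] e^{−σ²/2}` and a
matching variance deflation. Dividing each sampled draw by a freshly
drawn `e^ε` inverts the noise *per draw* but inflates the sampled
moments (`E[C e^{−ε}] = E[C] e^{+σ²/2}` plus a spurious `~σ²·mean²`
variance term), which systematically biases `σ` and the parameter
spreads downward. The default is therefore moment-consistent log-space
shrinkage: `log C_true = μ_c + α(log C_obs − μ_c)` with
`α = sqrt((s_c² − σ²)/s_c²)` (smoothed at the noise floor), which
reproduces the exact relations the reconstruction assumes. The
stochastic inversion remains available (`denoise="stochastic"`).

### Concentration–parameter correlations

The joint needs the cross-correlations between `log C` and the
parameters. Treating them as free time-invariant constants cannot
represent the structure the model itself induces (for the bolus model
`corr(log C, log ke)` runs from 0 at t=0 to −0.96 at 24 h), and the
resulting reconstruction bias collapses the spread estimates. The
default (`cross_corr_mode="model"`) derives them from the structural
model: for the bolus case, `cov(log C, log Vd) = −s_vd² − t E[ke] ρ s_vd
s_ke` exactly, and the ke leg from the exact log-normal decay ratios
`R_m(t) = E[ke e^{−m ke t}]/(E[ke] E[e^{−m ke t}])` evaluated by
Gauss–Hermite quadrature (differentiable). A single Gaussian copula
cannot match first- and second-order cross-moments simultaneously, so
the joint is calibrated to make the variance-derivative estimator
unbiased (ratio `R₂`) and the mean-channel derivative is rescaled by the
smooth factor `R₁/sqrt(R₂)`. Because shrinkage denoising rescales
covariances by `s_true/s_obs`, the calibration divides by the denoised
log-SD. For the mAb case the correlation uses the numerically evaluated
log-log sensitivity of the plasma profile to clearance. The parameter
correlation ρ is fixed at 0 in this mode — it is not identifiable from
per-time summaries, and when trained it drifts and corrupts the
propagated covariances; the freely trainable time-invariant mode remains
available (`cross_corr_mode="trainable"`).

### Case-specific loss structure

*Bolus case.* Plain squared losses (the profile spans one decade).
Initial-condition moments are sampled from `Dose/Vd · e^ε` with a draw
pool of at least 1000 (the IC moments are one-dimensional, so a large
pool is cheap and keeps the sampled-variance noise out of the gradient).

*mAb case.* Concentrations span three decades and derivatives five, and
different parameters live at different scales: the reflection
coefficients shape the fast early distribution phase while clearance
sets the tiny terminal slope. The data misfit is therefore linear + log
(the linear part drives the early fit, the log part pins the terminal
decay); each ODE residual enters twice, normalised once by the local
concentration scale and once by the local derivative magnitude (weights
held constant within an iteration, IRLS-style); the mean-channel
expectation is evaluated in closed form under the assembled joint — the
terminal plasma rate is a small difference of large fluxes, so a sampled
average would need thousands of draws to resolve it — while the variance
channel keeps the sampled estimators; and all states are anchored to
zero at t = 0 (the system is drug-free before dosing). The SD channel
follows the chain rule `dSD/dt = (dVar/dt)/(2 SD)`; an alternative
convention applying a squared span factor to that channel is available
behind `squared_sd_span_scaling`.

*Both cases.* The physics terms are switched off for the first 3000
iterations (data + IC only) and ramped in over 2000 iterations in the
mAb case, so the moment curves settle before the ODE residuals act.

### Initialisation

Means: log-linear regression of the observed means (bolus: slope → ke,
intercept → Vd) or a noncompartmental `dose/AUC` clearance (mAb).
Spreads (bolus): the structural model implies `Var(log C)(t) = (s_vd² +
σ²) + t² Var(ke)`, so a quadratic regression of the observed
log-variances yields a method-of-moments start. The time-constant part
is a ridge — persistent (Vd) and iid (ε) variability both contribute a
time-constant log-variance and per-time summaries cannot separate them —
so σ starts at 0.1 (typical assay noise) and Vd variability takes the
remainder. Correlation raws start at 0; reflection raws at 0
(σ1 = 0.5, σ2 = 0.25).

## Hierarchical MCMC benchmark

Three tiers: log-normal likelihood on the per-time mean and SD
summaries; individual clearances `CL_j = exp(μ_CL + τ_CL z_j)` with the
mPBPK solved exactly per subject and multiplicative measurement error;
weakly-informative priors (normal on `μ_CL` centred at log 0.012 L/h,
half-normal on `τ_CL` and the two summary scales, standard normal on the
logit-scale reflection raws — not the original authors' values, which
are unpublished). Body weights are pre-assigned and fixed; the
measurement-error innovations are drawn once per run and held fixed so
the log density is deterministic (an ensemble sampler cannot target a
stochastic density). Sampling uses emcee's affine-invariant ensemble;
split R-hat and ESS are computed by folding the walkers into four
pseudo-chains through arviz.

## Evaluation

APE/MAPE against known simulation truth; kernel-density-ready samples
for distribution comparison; Monte-Carlo prediction bands (parameter
draws from the fitted population, proportional error with SD 0.1 by
default, empirical 2.5/50/97.5 percentiles) with a coverage checker over
fresh subjects.

## What the generator emulates — and does not

The cohort simulator reproduces the study designs above exactly:
multivariate log-normal parameters, closed-form or eigensolver
profiles, iid log-normal measurement error (optionally frozen across
scenarios), uniform missingness, and (n−1)-variance aggregation. It does
not emulate below-quantification censoring, dropout that correlates with
exposure, model misspecification (the estimator assumes the true
structural and distributional model), covariates beyond body weight, or
reported-data pathologies such as digitisation error. Passing tests
therefore demonstrate recovery under a correctly specified model, not
robustness to real-world reporting artifacts.

## Problem sizes and identifiability limits

The flagship bolus fit uses the full budget (30 000 iterations,
N_cp = N_samples = 100, ≈3 min on one CPU). Sensitivity sweeps
(loss-weight rows, sampling-size trend) run at 8000–10 000 iterations;
the recovery checks use three independently simulated cohorts and
compare the median estimate per parameter; the mAb fits use 60
collocation points and 100–150 draws. These sizes are the package's
test-time choices and are deliberately smaller than an exhaustive
replication sweep.

Thirty-subject summaries carry limited information. An exact-model
least-squares oracle applied to the same simulated realisations shows
`ke`-mean errors of 10–12% for two of three arbitrary seeds (the sample
mean at late times has ≈24% SE) and 25–40% realisation noise in the
time-constant log-variance; the heavy upper tail of the log-normal also
biases small-sample variance estimates low, so `σ_ke` is systematically
underestimated by roughly a third at this design — by any estimator fed
these summaries. Recovery tolerances tighter than these bounds cannot be
met on arbitrary seeds, which is why the spread-parameter checks use
median-of-three and generous bands. The `(σ_Vd, σ)` split rides a nearly
flat ridge (see Initialisation) and the fitted σ typically lands 10–25%
below its anchor.

## Known limitations

* The joint Gaussian-copula/log-normal approximation is exact only at
  t = 0; its residual misfit grows with parameter CV and time span.
* Latent (unobserved) compartments are network outputs constrained only
  through their ODE channels; with finite residual tolerance this leaves
  weakly-identified directions in the mAb parameter space, and clearance
  recovery there is markedly harder than for the benchmark sampler,
  which solves the latent states exactly.
* Correlation parameters (between parameters, or parameter–state) are
  not estimable from mean/variance summaries; the model-consistent mode
  fixes them by construction.
* Sample-size information (n per time point) is carried through the data
  structures but not exploited by the likelihood-free loss.
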