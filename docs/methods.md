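# Methods

## The task and what the model infers

The modified inherent value of choice task (MIVCT) interleaves 27 free-choice
and 27 computer-instructed trials of a two-armed probabilistic reward task
(yellow vs blue stimulus, 80:20 reinforcement of the good stimulus, no
reversals). Computer selections on noChoice trials replay the participant's
own selections with a three-trial lag, so reward histories are matched across
conditions. Each trial has three phases — Cue (condition revealed),
Selection, Outcome — separated by uniform jitters (default 2–6 s).

The analysis treats behaviour as the output of a binary Hierarchical
Gaussian Filter (HGF) run as two *parallel hierarchies*, one per condition.
Level 1 is the binary input `u = 1[yellow was the rewarded card]`, which is
observable in both conditions from the selected card and its reward. Level 2
is the logit-scale tendency for yellow to be rewarding — in the Choice
hierarchy this is read as the self-efficacy belief `mu_self`, in the
noChoice hierarchy as `mu_other` — and level 3 (3-level variants) is the
log-volatility of that tendency. The predictive level-2 variance
`sigma_hat2` is the uncertainty `sigma_self` / `sigma_other`.

## Update equations

Per trial, with predictive quantities (hats) computed before the outcome:

    mu_hat1   = sigmoid(mu2)
    delta1    = u - mu_hat1
    sigma_hat2 = sigma2 + exp(kappa*mu3 + omega2)      (2-level: exp(omega2))
    pi2'      = 1/sigma_hat2 + mu_hat1*(1 - mu_hat1)
    sigma2'   = 1/pi2';   mu2' = mu2 + sigma2' * delta1

which is the precision-ratio update `delta_mu_i = (pi_hat_{i-1}/pi_i) *
delta_{i-1}` with the binary-input identification `pi_hat1 =
1/(mu_hat1*(1-mu_hat1))`. The 3-level variant adds the volatility prediction
error `delta2 = (sigma2' + (mu2'-mu2)^2)/sigma_hat2 - 1` and the standard
weighted level-3 update; a non-positive level-3 posterior precision (possible
at extreme parameters) raises an error that model fitting maps to log-joint
= -inf. The coupling `kappa` is fixed at 1 and initial states are fixed at
`mu2_0 = 0, sigma2_0 = 1, mu3_0 = 1, sigma3_0 = 1` (conventional binary-HGF
defaults; all configurable, none estimated).

The production filter is a compiled array kernel (numba when available,
identical pure-Python loop otherwise); a deliberately naive scalar
re-implementation (`hgf_update`) serves as an independent oracle and is held
to 1e-12 agreement in the tests, including agreement on *which trial* a
precision failure occurs.

## Response models and the model space

Two response links map the Choice-hierarchy predictive belief to
p(choose yellow):

* **softmax** (free decision noise `beta` per condition). The default is the
  symmetric form `1/(1+exp(-beta*(2*mu_hat1-1)))`, which returns 0.5 at
  belief indifference; the asymmetric form `1/(1+exp(-beta*mu_hat1))` is kept
  behind `form="verbatim"` because it appears in print, but it implies
  p > 0.5 at indifference, which contradicts decision-noise semantics.
* **unit-square sigmoid** `mu^zeta/(mu^zeta+(1-mu)^zeta)` with no free
  parameter: `zeta = -log(sigma_hat2)` of the acting condition, so greater
  certainty yields more deterministic choice. Since `sigma_hat2 >= 1` would
  give a flat or inverted link, `zeta` is floored at 1e-3.

A Rescorla-Wagner learner (fixed learning rate `alpha`, shared softmax
`beta`, separate per-condition value traces) is the non-hierarchical
control. The model space is exactly five architectures: {2-level, 3-level}
x {softmax, unit-square} plus RW+softmax.

The response likelihood scores **Choice trials only** by default: noChoice
selections are deterministic given history (yoking), so they inform beliefs
but not free decisions. Scoring them as predictions of the yoked computer
selection is available via `score_nochoice=True`.

## Fitting, evidence, model selection

MAP estimation works in an unconstrained estimation space (identity
transform for evolution rates, log for `beta`, logit for `alpha`) with
Gaussian priors `omega2 ~ N(-3, 4^2)`, `omega3 ~ N(-6, 4^2)`,
`log beta ~ N(0, 2^2)`, `logit alpha ~ N(0, 1)`. Optimization is
multi-start L-BFGS (default 8 starts: the prior mean plus dispersed draws);
ties within 1e-9 resolve to the smallest parameter norm. Log model evidence
is the Laplace approximation at the MAP with a central finite-difference
Hessian whose eigenvalues are floored at 1e-6 — an approximation to the
negative variational free energy. The chance diagnostic is the geometric
mean per-trial likelihood `exp(-NLL/n)`, compared to a 0.55 criterion
(a coin-flip response model scores exactly 0.5); the raw NLL-per-trial
reading is reported alongside because the criterion is sometimes quoted on
that scale.

Random-effects Bayesian model selection follows the variational Dirichlet
scheme iterated to convergence (the converged assignments include the
digamma feedback of the fixed point, as in the reference MATLAB
implementation). Exceedance probabilities come from Monte-Carlo Dirichlet
sampling (default 1e6 draws); the Bayes omnibus risk compares the
random-effects free energy with the fixed uniform-frequency null, and
`pxp = xp*(1-bor) + bor/M`.

## fMRI stage

For each subject, Cue-phase regressors per condition are parametrically
modulated by the belief (`mu`, SE-B design) or uncertainty (`sigma`, SE-U
design) trajectory of the winning model, mean-centred within condition
before convolution with a canonical double-gamma HRF (peak 6 s, undershoot
16 s, ratio 6, no derivatives) on a microtime grid (TR/16). Belief and
uncertainty designs are separate GLMs because the two trajectories are
correlated. Selection and Outcome events, a discrete-cosine high-pass basis
(128 s cutoff) and optional nuisance columns complete the design. Fitting is
OLS with optional one-pass AR(1) prewhitening; the SE-B/SE-U contrast is the
modulator-beta difference self - other. Whole-brain voxelwise inference is
out of scope: synthetic region time series (`y = X*beta + AR(1) noise`)
validate regressor construction, contrast logic and group-level one-sample
tests, and `extract_eigenvariate` provides the first-eigenvariate summary
used downstream.

## Association stage

Sparse PLS (regression mode, NIPALS iterations with soft-thresholding that
retains the `keep_x`/`keep_y` largest loadings per component; deflation by
the X-score regression) relates brain contrast values (X) to the
psychometric battery (Y), both z-scored within training data. Tuning is
two-step with repeated 4-fold cross-validation: first the sizes minimizing
held-out MSEP, then per-variable selection frequencies over `repeats x
folds` refits, with stable sets at frequency >= 0.8. The size grid always
includes a 0-component option (training-mean predictor): when sPLS does not
beat the mean out of sample, nothing is selected — without this guard, the
fixed sample's largest chance correlation is re-selected across CV refits in
a material fraction of pure-noise datasets at n = 21. Confirmatory
statistics use OLS (no multiplicity adjustment, matching the reporting
convention); symptom-level structure uses backward stepwise OLS under AIC
(drop the predictor whose removal most decreases AIC; ties drop the larger
column index; intercept always kept).

## Synthetic cohorts

`generate_cohort` draws per-subject evolution rates from the population
estimates of the reference sample — `omega2_Choice ~ N(-6.10, 2.21^2)`,
`omega2_noChoice ~ N(-6.33, 0.978^2)`, `omega3 ~ N(-6.00, 0.019^2)` — with
draws whose filter loses positive precision rejected and redrawn (the
population is truncated to the numerically valid region). Softmax agents
draw `log beta ~ N(log 4, 0.5^2)`. Each agent plays a fresh schedule closed
loop. The psychometric battery (PHQ-9 items and total, GCOS-CP subscales,
PCASS subscales, BRS) is generated from two latents — one tied to the
standardized model-derived statistic mean(`sigma_self`) - mean(`sigma_other`),
one an independent depression factor — through a loading matrix (defaults
load the brain latent on the depressive items, perceived choice negatively,
and the impersonal orientation), then mapped onto realistic scale ranges
(items 0-3; scale means/SDs from a moderately depressed young-adult
sample). `planted_association_data` provides the simpler Gaussian
planted-structure matrices used by the sPLS recovery tests.

What the generator does **not** emulate: real response times and lapses,
perseveration and other non-Bayesian choice heuristics, scanner noise
structure beyond AR(1), item-level measurement models, or missing data.
Passing recovery tests therefore demonstrates internal consistency of the
pipeline, not validity for any particular empirical dataset.

## Problem sizes and numerical choices

Recovery suites run at sizes chosen to give stable Monte-Carlo behaviour on
a single CPU: parameter recovery uses 40 sessions of 270 trials; model
recovery 10 cohorts of 21 subjects at 270 trials; GLM recovery 10 cohorts of
21 subjects plus 100 null simulations; sPLS stability uses 100 CV repeats
(the CLI default remains 1000). Optimizer tolerance is 1e-7 (ftol);
objective pathologies map to a 1e10 sentinel rather than inf so
finite-difference gradients stay usable.

## Known limitations and honest failures

* **Refit likelihood ceiling.** Agents simulated from the 3-level
  unit-square model at population `omega2 ~ -6` choose stochastically early
  in a session (the unit-square slope starts near zero when `sigma2_0 = 1`),
  so the median refit per-trial likelihood of a synthetic cohort sits around
  0.55-0.60 — above the 0.55 chance criterion in most replicate cohorts but
  below the 0.662 median reported for real participants, whose behaviour was
  more deterministic than a self-consistent agent at these parameters can
  be. The MAP refit exactly attains the generating-parameter likelihood, so
  this is a property of the generative regime, not of the optimizer.
* **Three-level recovery in a stationary task.** The MIVCT has no
  reversals, so the volatility level barely expresses in behaviour:
  cohorts generated from the 3-level unit-square model are fitted equally
  well (max log-likelihood within 0.05) by the 2-level variant, which then
  wins model selection by a small Occam margin. Group-level BMS therefore
  selects 2L+unit-square on such synthetic cohorts — correct parsimony
  behaviour, and a caution that the 3-level architecture's empirical success
  must rest on behavioural features the synthetic agents do not produce.
* Laplace evidence is a local approximation; strongly multimodal posteriors
  (rare at these trial counts) would need MCMC, which is out of scope.
* The stepwise-AIC null keeps ~1 noise predictor in about a third of
  datasets (expected for AIC's 15.7% per-variable retention rate); AIC is
  used for fidelity with the analysis being reproduced, not as the best
  sparsity control.
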