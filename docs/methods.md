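# Methods

## The model

The package centers on a risk-sensitive extension of Rescorla–Wagner
(delta-rule) learning for two-option risky choice, here called PEIRS
(prediction-error–induced risk seeking). For every stimulus *c* the
learner keeps two running estimates, both in reward points:

- a mean estimate, updated after each outcome *r*:
  Q ← Q + α_Q (r − Q)
- a spread estimate, updated toward the unsigned prediction error:
  S ← S + α_S (|r − Q| − S)

With i.i.d. rewards and a converged Q, the fixed point of S is the
mean absolute deviation of the reward distribution, σ·√(2/π) for a
Gaussian. The deviation term is unsigned by construction: S must stay
a dispersion estimate, and the signed version would relax to zero and
make the risk terms vacuous.

Choice utilities combine the two with a context-dependent risk weight:

U = Q + γ₀·S + γ₁·δ_context·S

where δ_context is the mean Q of the offered stimuli minus the mean Q
over all four stimuli of the active set — positive in rich contexts,
negative in poor ones, computed from the agent's *current* estimates
rather than the true means (the true-mean values are +15/−15 points
for the default 35/65 design). γ₀ expresses a baseline taste for
variance; γ₁ > 0 produces risk seeking in rich contexts and risk
aversion in poor ones. With γ₀ = γ₁ = 0 the model is exactly RW
(U = Q), the nested baseline used for model comparison.

Two-option choices follow a logistic (softmax) rule with inverse
temperature β on the utility difference. Forced single-option trials
are taken with probability 1: they update Q and S but contribute no
choice-likelihood term, because a probability-1 event carries no
information about β or the risk weights.

All latent states start at Q = 50, S = 5 points. When the stimulus set
is replaced mid-session (after two blocks), the new stimuli start from
these initial values and δ_context averages over the new set only.

## Task designs

**Experience task.** Four stimuli in a 2×2 design — mean 35 or 65
points, SD 5 or 20 — over 4 blocks × 72 trials: per block 18
high-context trials (the two mean-65 stimuli), 18 low-context (the two
mean-35), 24 mixed (one of each mean, the four pairings balanced), and
12 forced trials (3 per stimulus). Blocks 1–2 use stimulus set A–D,
blocks 3–4 the structurally identical set E–H. A forced trial showing
stimulus X never immediately precedes a context trial offering X
(enforced across block boundaries by constrained shuffling with swap
repair; a generation error names the offending block if the bounded
repair budget is exhausted).

Rewards are drawn per block: for each stimulus one sequence of
block-length draws, affinely rescaled so its empirical mean and SD
equal the specification exactly before rounding, then delivered in
order, rounded to integer points and clipped to the 0–100 display
scale. Clipping is rare (≥1.75 SD for the widest spec) and biases the
widest high-mean stimulus by at most ~0.6 points.

**Description task.** Ten fixed gambles, each played twice per block
over 4 blocks × 20 trials. Gambles 1–8 ("mixed"): a 50:50 ±10 coin
flip (EV 0) against a risky option from the cross of win-probability
{0.6, 0.4} × win {30, 70} × loss {30, 70}, spanning EV −30…+30.
Gambles 9/10 are EV-matched safe-vs-risky pairs in a pure-loss and a
pure-gain context; only the equal-EV and valence-mirror constraints
are fixed by the design, so the point values default to
{certain −40 vs 50:50 −80/0} and {certain +40 vs 50:50 +80/0} and are
configurable. Presentation order is a function of the seed alone, so
both sessions of a crossover reuse the same order.

## Behavioral statistics

Risk preference per context is the proportion of matched-mean choice
trials on which the high-SD option was chosen. For the experience task
it is computed over the second half of each 144-trial stimulus set
(learning has stabilized; mixed-trial accuracy, the comprehension
control, uses all mixed trials). For the description task all 8
repetitions of gambles 9 and 10 count, and accuracy comes from gambles
1–8 as the fraction of higher-EV choices.

The 2×2 within-subject ANOVA is computed from per-subject
difference-score contrasts: each effect's F is the square of the
paired t on its contrast with df = (1, n−1), which is exact for a
fully-within 2×2 design; partial η² = F/(F + df₂). The Wilcoxon
signed-rank routine drops zero differences, midranks ties, and uses
the normal approximation with a 0.5 continuity correction and tie
variance correction.

Model-derived stimulus utilities use the end-of-set Q/S values with a
single-stimulus context signal (δ = Q_stimulus − mean Q), mirroring a
rating situation where one stimulus is shown at a time.

## Hierarchical fitting

Parameters are estimated on an unconstrained scale — logit for the
learning rates, log for β, identity for the γs — where the population
distribution is an independent Gaussian per parameter. The
empirical-Bayes EM alternates:

- **E-step:** per-subject MAP estimates under the current prior
  (multistart L-BFGS-B: prior mean, prior draws, and from the second
  iteration the previous MAP as warm start; objective tolerance 1e-9),
  with Laplace posterior variances from the finite-difference Hessian
  of the negative log posterior (inverse-Hessian diagonal; fallback to
  diagonal curvature, then to the prior variance for likelihood-flat
  directions).
- **M-step:** prior mean = cohort mean of the MAPs; prior variance =
  mean of (MAP² + posterior variance) − mean², floored at 1e-6.

Iteration stops when the largest absolute change in any prior moment
falls below 1e-3 (default cap 100 iterations). Conditions are fitted
separately. The RW baseline shares the parameter space with γ₀ = γ₁
pinned at 0; its likelihood does not depend on α_S, which therefore
stays at the prior — it is carried for structural symmetry and the BIC
penalty counts k = 3 (RW) vs k = 5 (PEIRS).

Per-subject BIC = −2·loglik(MAP) + k·ln(n choice trials), with forced
trials excluded from n; cohort totals are sums of per-subject BICs.

## Synthetic populations (the study conditions)

Cohorts are sampled from Gaussian populations on the unconstrained
scale. The defaults encode the study conditions the analyses target:

| parameter | sated loc | hungry loc | scale |
|---|---|---|---|
| α_Q (logit) | logit 0.3 | logit 0.3 | 0.7 |
| α_S (logit) | logit 0.3 | logit 0.3 − 0.735 | 0.7 |
| β (log) | log 0.15 | log 0.15 | 0.5 |
| γ₀ | 0 | 0 | 0.15 |
| γ₁ | 0.045 | 0.045 − 0.0165 | 0.02 |

Rationale: β ≈ 0.15 on the points scale puts mixed-trial accuracy
above 90%, matching the reported comprehension-control behavior; γ₀ is
centered at zero (overall risk-taking is neutral); γ₁'s location is
calibrated so the truth-level PEIRS-vs-RW evidence per session,
averaged over the two conditions, matches the reported cohort BIC gap
(≈14 BIC per session). The hungry regime lowers α_S and γ₁ only, in
the reported 0.70:0.55 effect-size ratio, with the shift magnitude
calibrated so the cohort-level hunger × context interaction lands near
the reported F ≈ 8.4 at n = 32. Crossover cohorts are generated by
drawing each subject once from the sated population and applying the
fixed location shift for that subject's hungry session, giving the
within-subject pairing of the design.

A separate, deliberately dispersed population drives parameter
recovery: loc (logit 0.3, logit 0.3, log 0.5, 0, 0.08), scale (1.0,
1.0, 0.5, 0.3, 0.05). Recovery probes the fitting procedure across the
range of parameters the task can identify; the spread learning rate is
informative only through the risk terms, so the recovery regime sits
where β and γ₁ make the spread signal visible (likelihood profiling
shows the session likelihood is nearly flat in α_S when β·γ₁ is small,
and recovery of α_S would fail there for any estimator).

The description-task generator is policy-based (no learning): the
default fixture is a diminishing-sensitivity value policy
v(x) = sign(x)·|x|^0.8, which is risk-averse for gains and
risk-seeking for losses — the reversed, description-side context
pattern — plus a logistic-in-(ΔEV, Δspread) family for custom
fixtures.

## What the synthetic data do and do not emulate

The generator reproduces the tasks' trial structure, reward
statistics, forced-trial bookkeeping, the within-subject crossover,
and choice behavior driven exactly by the fitted model family. It does
not emulate reaction times, rating scales, attention lapses,
perseveration/choice-kernel effects, session-order effects, or any
divergence between participants' learning and the model class itself.
Passing tests therefore validate the pipeline's internal consistency
(the fitting recovers what generated the data; the statistics detect
the effects built into the generator) — they do not certify that real
participants follow this model.

## Numerical choices

- Likelihood and log-sigmoid computed in log space; no probability
  floors (the logistic is bounded away from 0 for finite arguments,
  and the argument is clamped only via β ≤ e^50).
- The logistic transform is clipped a hair inside (0, 1) so extreme
  optimizer excursions cannot produce boundary learning rates.
- Optimizer search box ±25 on the unconstrained scale (generous: a
  logit of ±25 is numerically saturated anyway).
- Finite-difference step for the Laplace Hessian: 1e-3.
- Seeds are hierarchical (`numpy` SeedSequence spawning): one stream
  per subject for schedule and choices, so enlarging a cohort never
  perturbs existing subjects.
- The compiled (numba) likelihood kernel is cross-checked against a
  pure-python replay to machine precision in the test suite.

## Problem sizes

Defaults used by the test suite and the acceptance script: 32-subject
cohorts, 288-trial sessions (240 choice trials), 50 replicate cohorts
for the interaction power check, 1,000-seed schedule sweeps, 10
multistart optimizations on the first EM iteration and 3 thereafter.
These sizes reproduce the study-scale analyses exactly; nothing is
scaled down.

## Known limitations

- The E-step's Laplace approximation uses the curvature at the MAP;
  for strongly skewed subject posteriors (e.g., β against its lower
  identifiability edge) the posterior variance is approximate, which
  can slightly mis-calibrate prior shrinkage.
- BIC is computed at the MAP (the convention adopted here, since the
  pipeline never computes unregularized MLEs), which is conservative
  toward the richer model relative to an MLE-based BIC.
- With 32 subjects, the true-vs-recovered cross-correlation matrix
  carries sampling noise of SD ≈ 1/√29 ≈ 0.19 per cell; the maximum
  absolute off-diagonal of even a perfect estimator is therefore
  around 0.3 for a median seed, and the spurious-correlation bound
  should be read with that in mind.
- Near-deterministic choice regimes (large β) identify β only from
  below; the degenerate-population tests use moderate β for this
  reason.
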