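# Methods

## The behavioural model

`cuetd` analyses intertemporal choice under cue exposure: on every trial a
participant chooses between a fixed immediate reward (smaller-sooner, SS;
20 € at delay 0) and a larger delayed reward (larger-later, LL; amount *A*
at delay *D* days).  Choices come from two sessions per subject — one after
neutral and one after appetitive (erotic) cue exposure — and the scientific
question is whether cue exposure shifts the discounting process.

Subjective value of the LL follows hyperbolic discounting with a
delay-independent multiplicative offset:

    SV(LL) = ω(t) · A / (1 + k(t) · D)          with  ω ∈ (0, 1]
    SV(SS) = 20                                  (never discounted or offset)

Condition effects enter as additive per-subject shifts gated by the
dummy-coded indicator I_Ero(t) ∈ {0, 1}:

    k(t) = exp(k_neut + I_Ero(t) · S_k)          (shift in log space)
    β(t) = β_neut + I_Ero(t) · S_β
    ω(t) = logistic(λ_neut + I_Ero(t) · S_λ),    λ = logit ω

Choice follows a softmax (logistic) rule on the value difference:

    P(LL) = logistic(β(t) · [SV(LL) − SV(SS)])

Two variants are compared.  The **Base-model** fixes ω ≡ 1 (pure hyperbolic
discounting).  The **Offset-model** estimates ω_neut and its condition
shift; ω < 1 captures a delay-independent bias against the delayed option —
e.g. a flat cost of waiting, or distrust in delayed payout — that a discount
rate alone cannot absorb, because an offset depresses LL value equally at
all delays while k acts multiplicatively with delay.

Assumptions worth keeping in mind: value is separable from delay exactly as
the hyperbola prescribes; β is allowed to go negative if the shift drives it
there (the equations are applied literally; a warning is logged because a
negative β means choices anti-correlate with value); invalid trials (missed
response window) carry no information and are excluded from every
likelihood and from the model-agnostic SS-proportion measure.

## Hierarchy and priors

Each parameter family f ∈ {log k, S_k, β, S_β, λ, S_λ} has a group-level
Gaussian: subject value = μ_f + σ_f·z, z ~ N(0,1) (non-centered
parameterisation, which removes the funnel geometry that otherwise defeats
gradient-based samplers on hierarchical models).

Group-mean priors (informative, carried over from earlier work with this
task):

| parameter | prior |
|---|---|
| log k | Normal(−4.2, 2.01) |
| S_k   | Normal(0.15, 0.64) |
| β     | Normal(0.51, 0.30) |
| S_β   | Normal(0.02, 0.11) |
| ω     | Uniform(0, 1) |
| S_ω   | Normal(0, 0.40) |

The Uniform(0,1) prior on the group-mean ω is implemented as a
standard-logistic density on μ_λ = logit(μ_ω).  The S_ω prior is taken on
the logit-shift scale.  Composing ω and its shift on the logit scale is a
deliberate design choice: the literal additive form ω_neut + I·S_ω can
leave (0, 1], and nothing in the model definition prevents that; the
logistic composition keeps every effective offset strictly inside (0, 1)
for any draw while reducing to the additive form to first order for small
shifts.  Group SDs, which the model definition leaves open, get
half-Normal(0, 1) priors — weakly informative shrinkage on the scales all
six families live on (log/logit units of order 1).

## Sampling

The posterior is explored with an in-package no-U-turn sampler (dynamic
Hamiltonian Monte Carlo with slice sampling across the doubling trajectory)
using hand-derived analytic gradients of the joint log posterior.  Step
size is tuned by dual averaging to a 0.9 target acceptance statistic
(higher than the generic 0.8 default because the group-SD parameters of
hierarchical models mix noticeably better with the smaller steps); a
diagonal inverse mass matrix is estimated from warmup draws over doubling
memory windows (mass updates trigger a step-size reset).  Maximum tree
depth is 10; trajectories whose joint density drops more than 1000 nats
below the initial energy are flagged divergent.  The numerically sensitive
pieces are guarded: exponents are clipped at ±30 (a logistic at ±30 differs
from its limit by < 1e−13, so the clip is bias-free in practice but keeps
gradients finite), and log-probabilities use log1p/softplus forms.

The study-scale configuration is 4 chains, 1500 warmup iterations and 4000
retained draws in total.  Tests and the acceptance script use a desk-scale
configuration — 2 chains, 400 warmup, 400 retained draws per chain, 36
subjects for recovery and 12 subjects for model-comparison replicates —
sizes chosen so the full pipeline runs on a single CPU in minutes while
keeping Monte-Carlo error well below the effects being checked.

Convergence is gated on the split-chain potential scale reduction factor
(R-hat, via arviz), with 1 ≤ R-hat < 1.05 acceptable; parameters with zero
variance across all chains (e.g. shift parameters pinned to 0 in a
single-condition fit) are reported as R-hat 1 with a zero-variance flag
rather than left undefined.  The per-trial likelihood/gradient kernel is
numba-compiled, with a pure-numpy reference implementation kept alongside;
the two are verified against each other and against finite differences in
the test suite.

## Model evaluation

**WAIC** is computed from the per-trial pointwise log-likelihood matrix on
the deviance scale: lppd_i = log mean_s exp(ll_si), p_i = var_s(ll_si),
WAIC = −2 Σ_i (lppd_i − p_i), with a standard error from the across-trial
spread of the pointwise contributions.  Lower is better; ranking ties break
by fewer group-level parameters, then by name.  The pointwise unit is the
trial, so WAIC magnitudes scale with the total valid-trial count.

**Posterior predictive checks** simulate one full dataset per selected
posterior draw (each subject keeps their own trials and condition
indicators) and compare the group-mean fraction of LL choices per delay bin
with the observed data.  The eight bins are the Set-1 delays
{1, 3, 5, 8, 14, 30, 60, 122}; Set-2 delays map to the nearest Set-1 delay
(ties to the smaller), which coincides with matching delays by rank.  A fit
is considered descriptively adequate when the observed bin means fall
inside the simulated central 95% interval in ≥ 90% of bins.

**Choice-prediction accuracy** is the fraction of trials on which the
higher-probability option at the posterior-mean subject parameters matches
the observed choice.  Point estimates rather than draw-averaged
probabilities are the documented default; the two differ little for
well-concentrated posteriors.

## Hypothesis evaluation

Highest density intervals are computed exactly on the sorted draws: the
shortest window containing ⌈mass·n⌉ order statistics.  Savage-Dickey BF01
for a point null divides a Gaussian-kernel estimate (Silverman bandwidth)
of the posterior density at the null by the prior density there; a
moment-matched normal approximation is available as an option.  The
directional Bayes factor is the ratio of posterior mass below zero to mass
above zero, with exact zeros counted to neither side and an empty side
capped at one draw (with a warning).  Evidence labels follow the usual
thresholds: (1, 3] anecdotal, (3, 10] moderate, > 10 strong, mirrored via
reciprocals.  Bayesian correlations use the default uniform prior on ρ
(stretched beta, κ = 1) with BF01 obtained by quadrature of the correlation
likelihood kernel; the shift-parameter report table gives posterior mean,
SD, dBF, BF01 and 85%/95% HDIs per shift, each on its native model scale
(log-k, β and logit-ω units respectively).

## The synthetic-task generator

`simulate_cohort` emulates the study design: 16 multipliers × 8 delays =
128 trials per condition, two multiplier/delay sets counterbalanced across
subjects (deterministically alternating by subject index; random assignment
is available as an option), subjects drawn from the group-level Gaussians
above (λ on the logit scale), and choices drawn from the softmax model.
Default group means are the prior means; default group SDs (1.0 for log k,
0.5 for S_k, 0.2 for β, 0.1 for S_β, 0.5 for λ, 0.2 for S_λ) reflect the
between-subject spread typical of delay-discounting cohorts: roughly a
±2.7-fold range of discount rates across the central 95% of subjects and
offsets spanning ~(0.27, 0.73) around a central 0.5.  An optional miss rate
injects INVALID trials to exercise the exclusion path (default 0).

What the generator does *not* emulate — and therefore what passing
recovery/PPC tests cannot certify about real data: response times and any
speed–value coupling, within-session learning or fatigue drifts,
presentation-order effects, stimulus-level (image) variation in cue
potency, and model misspecification of the discount function itself (real
choice data may be non-hyperbolic in ways the generator never produces).
Recovery results certify the inference machinery, not the model's truth.

## Degenerate subjects

A subject whose minority-option count pooled over both conditions falls
below a threshold (default 2 — e.g. a single SS choice in 256 trials)
is excluded before fitting and logged.  Such patterns leave the discount
rate unidentified (any k small enough fits equally well) and produce
extreme, prior-dominated subject estimates.  The threshold is a documented
operationalisation of "essentially one-sided responding"; it is exposed as
a parameter and a threshold of 0 disables exclusion.

## Numerical and degenerate-input choices

- Softmax and log-likelihoods use overflow-safe logistic forms; trial
  log-likelihoods are finite for all finite β and values.
- LL amounts are rounded to euro cents when designs are built.
- WAIC requires ≥ 2 draws (the pointwise variance is otherwise undefined)
  and errors out rather than guessing.
- `hdi` and the Bayes-factor routines require ≥ 100 draws; constant draws
  yield a zero-width interval.
- R-hat with a single chain is a configuration error, not a silent 1.0.
- Pooled two-sample t-tests from summary statistics error on zero pooled
  variance.  Reconstructed t-statistics match originally reported ones only
  when the original test was a pooled-variance test on the same summaries;
  mismatches (e.g. Welch corrections, paired designs, raw-data analyses)
  are possible and such values should not be force-reconciled.

## Known limitations

- The sampler adapts a diagonal mass matrix only; posteriors with strong
  group-level correlations would mix better under a dense metric.
- Savage-Dickey BF01 inherits kernel-density bias at the null when the
  posterior is sharply peaked away from it; the analytic-normal option is
  more stable there but assumes posterior normality.
- WAIC standard errors are asymptotic in the trial count and optimistic
  when pointwise terms are strongly dependent within subjects.
- The Uniform(0,1) group-mean prior for ω is the only supported choice;
  the additive-shift variant of the offset (with rejection of out-of-range
  values) is available for single evaluations but not for fitting.
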