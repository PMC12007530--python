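# cuetd — cue-exposure effects on temporal discounting

`cuetd` is a hierarchical Bayesian analysis pipeline for intertemporal-choice
(delay-discounting) experiments with a within-subject cue-exposure
manipulation.  It is written for decision-neuroscience researchers who ask:
*does exposure to appetitive cues make people discount delayed rewards more
steeply, respond more noisily, or devalue the delayed option outright?*

On each trial a participant chooses between a fixed immediate reward
(smaller-sooner, SS: 20 € now) and a larger delayed reward (larger-later,
LL: amount *A* at delay *D* days); 16 amount multipliers × 8 delays give
128 trials per condition (neutral vs. erotic cue exposure).

## The model

Subjective value of the delayed option is hyperbolic with an optional
multiplicative offset ω ∈ (0, 1]:

```
SV(LL) = ω(t) · A / (1 + k(t) · D)        SV(SS) = 20
P(LL)  = logistic( β(t) · [SV(LL) − SV(SS)] )
```

Cue-condition effects are per-subject additive shifts gated by the indicator
I_Ero ∈ {0, 1}:

```
k(t) = exp( k_neut + I_Ero(t) · S_k )
β(t) = β_neut + I_Ero(t) · S_β
ω(t) = logistic( logit ω_neut + I_Ero(t) · S_ω )
```

The **Base-model** fixes ω ≡ 1; the **Offset-model** estimates ω and its
shift.  All parameters are hierarchical (group-level Gaussians,
non-centered), sampled with an in-package no-U-turn sampler using analytic
gradients.  Model comparison uses WAIC (deviance scale, lower = better);
hypothesis evaluation uses highest density intervals, Savage-Dickey BF01
against zero shifts, and directional Bayes factors (posterior mass below
vs. above zero).  A synthetic-cohort generator reproduces the task design so
the full pipeline is testable against known ground truth.  See
`docs/methods.md` for the complete model description and numerical choices.

## Worked example

Simulate a 12-subject cohort whose true subjective-value offset is 0.8, fit
both models, compare them, and summarise the condition-shift evidence:

```
$ cuetd simulate --n-subjects 12 --omega 0.8 --seed 11 --out-dir sim
wrote sim/choices.csv (24 datasets)

$ cuetd fit --data sim/choices.csv --variant offset --chains 2 \
        --warmup 400 --draws 800 --seed 21 --out-dir fit_offset
offset: WAIC 1285.5, max R-hat 1.026, choice accuracy 91.7%

$ cuetd fit --data sim/choices.csv --variant base --chains 2 \
        --warmup 400 --draws 800 --seed 22 --out-dir fit_base
base: WAIC 1755.2, max R-hat 1.029, choice accuracy 87.0%

$ cuetd compare --fit-dir fit_offset --fit-dir fit_base --out waic_table.csv
rank 1: offset WAIC 1285.5 (SE 52.9)
rank 2: base WAIC 1755.2 (SE 54.9)

$ cuetd bf --fit-dir fit_offset --out shift_bf.csv
mu_s_ero_k: mean +0.371 BF01 0.45 (anecdotal (alternative)) dBF 0.02
mu_s_ero_beta: mean +0.032 BF01 2.10 (anecdotal (null)) dBF 0.30
mu_s_ero_logit_omega: mean +0.165 BF01 1.45 (anecdotal (null)) dBF 0.09
```

Reading the output: both chains converged (R-hat < 1.05).  The Offset-model
wins the WAIC comparison by ~470 points — as it must, because the data were
generated with ω = 0.8, a 20% flat devaluation of the delayed option that
the Base-model can only absorb by distorting k — and predicts 91.7% of
choices at the posterior-mean parameters.  The `bf` table summarises the
group-mean shift parameters: each row gives the posterior mean and SD, the
Savage-Dickey BF01 (> 1 favours a zero shift), and the directional Bayes
factor dBF (posterior mass below zero ÷ mass above zero).  Here the
generating truth had a small positive k-shift (S_k = 0.15) and 12 subjects
are too few to resolve it decisively, so the evidence is anecdotal — with a
dBF of 0.02 leaning towards an increase (mass above zero dominates).

The same steps are available as library calls (`simulate_cohort`,
`fit_model`, `waic`, `rank_models`, `shift_report`,
`posterior_predictive_simulate`); the CLI is a thin wrapper.  `cuetd ppc`
exports observed vs. simulated LL-choice fractions per delay bin, and
`cuetd report` consolidates a run directory into JSON/Markdown.

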