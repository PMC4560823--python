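# Methods

## Task model

The simulated task is a within-subject 2×2 contextual bandit. A *context*
is a fixed pair of options presented together throughout a session; the
four contexts per session cross outcome valence (reward: win +0.5 € vs
0 €; punishment: lose −0.5 € vs 0 €) with feedback information (partial:
only the chosen option's outcome is shown; complete: both outcomes are
shown). Within a context the two options deliver their non-zero outcome
with reciprocal probabilities 0.75/0.25, drawn independently per option on
every trial — so in complete-feedback contexts both options show the same
outcome on 2 · 0.75 · 0.25 = 37.5 % of trials. Each context appears 24
times per session (96 trials), each of 4 sessions introduces 8 novel
options, and a final 112-trial transfer test presents all 28 unordered
pairs of the last session's options 4 times each with no feedback.

Design choices where the task description is underdetermined:

- *Pseudorandom interleaving* is constrained shuffling with no context
  more than 4 consecutive trials; the cap is a mild guess that mimics
  "unpredictable" interleaving and has no effect on the model mathematics.
- *Side counterbalancing*: each option appears on the left on exactly half
  of its presentations (12/24 in learning; 2/4 per transfer pair).
- Outcomes are stored in euros (±0.5, 0); reporting utilities convert to
  cents. Expected values per option are therefore ±37.5 ¢ and ±12.5 ¢.
- Missed responses are not modelled: synthetic agents always respond, and
  the table readers reject rows with missing choices.
- Option identity is session-scoped (32 options in total), so learned
  values never carry across sessions; Q and V start at 0 — the symmetric
  choice for novel options of unknown valence.

## Learning models

Both agents choose with a two-option softmax with inverse temperature β,
computed through the logistic of β·ΔQ for numerical stability. ABSOLUTE
updates option values with the delta rule on factual outcomes (rate α₁)
and, when counterfactual feedback is available, on the unchosen option
(rate α₂). RELATIVE additionally learns a context value V(s) at rate α₃
from the context-level outcome R_V — the mean of factual and
counterfactual outcomes, with the current Q(s,u) standing proxy for the
unseen counterfactual under partial feedback — and centres both option
prediction errors on V(s). V(s) is learned in a random-policy manner
(independent of which option was chosen), making it a context reference
point rather than a policy value.

Within a trial, *all* prediction errors are evaluated on pre-update
(time-t) values and all increments applied afterwards; in partial
feedback, the unchosen Q is read for R_V before any update. One
learning-rate set is shared across valences. These conventions make the
reduction RELATIVE(α₃ = 0, V₀ = 0) ≡ ABSOLUTE exact, which the test suite
asserts trial-by-trial, and bound trajectories (ABSOLUTE Q ∈ [−0.5, 0.5];
RELATIVE V ∈ [−0.5, 0.5], Q ∈ [−1, 1]) by convexity.

The published group-mean parameters used as operating points throughout
(likelihood maximization): ABSOLUTE β = 17.4, α₁ = 0.28, α₂ = 0.18;
RELATIVE β = 21.52, α₁ = 0.19, α₂ = 0.15, α₃ = 0.33. MAP counterparts:
β = 11.4/13.66, α₁ = 0.29/0.20, α₂ = 0.20/0.16, α₃ = 0.34.

## Estimation

The likelihood of a subject's dataset is the product of one-step-ahead
softmax probabilities of the observed choices, obtained by replaying the
subject's own history of choices and outcomes; probabilities are floored
at 1e−12 inside logs. MAP estimation adds nearly flat priors chosen to
cover the plausible range: Beta(1.1, 1.1) per learning rate and
Gamma(shape 1.2, scale 5) for β. Optimization is multistart (default 20
random starts) bounded L-BFGS-B with α ∈ [10⁻⁶, 1 − 10⁻⁶] and
β ∈ [10⁻⁶, 100]; the β cap and the multistart count guard against the
occasional very sharp optimum and against local minima. Fits are
deterministic given the seed.

Criteria follow the deviance-scale reporting convention of the reference
comparison table: BIC = −2·LLmax + df·ln n with n = 384 (the per-subject
learning-test trial count — this choice reproduces the reported
BIC−deviance gaps of ≈18 and ≈24 under rounding), the reported AIC column
is −2·LLmax + 4·df, and the conventional AIC is exposed alongside. LPP is
the log posterior at the MAP point; the Gaussian curvature (Laplace) term
can be added with `laplace=True` but is off by default, since the pure
log-prior contribution already accounts for the reported −2·LPP vs −2·LL
gaps (≈7 for 3 parameters, ≈9 for 4).

## Model selection

Random-effects BMS treats the generating model as a random effect across
subjects. From the subjects × models log-evidence matrix (LPP values) the
variational Dirichlet–multinomial scheme alternates posterior model
assignments with Dirichlet count updates (prior α₀ = 1 per model, the
standard uniform choice) until the relative change in α drops below 1e−6.
PP = α/Σα; XP is estimated from 10⁶ Dirichlet posterior samples (Monte-
Carlo s.e. < 0.01), with the two-model closed form via the regularized
incomplete beta function kept as an independent cross-check in the tests.
Fixed-effects comparisons are paired two-sided t-tests on per-subject
criterion differences.

## Behavioural analyses

Learning performance is the per-context rate of choosing the most
advantageous option (G75 in reward, L25 in punishment contexts). Transfer
performance is each option's choice rate over all comparisons involving it
(28 trials per option); by construction the mean rate across the 8 options
is exactly 0.5. Transfer predictions use each subject's frozen
end-of-session-4 option values and the same β as the learning fit
(re-optimizing a transfer-specific β is not implemented, matching the
primary variant reported). Because no updating occurs, predictions are
invariant to trial order.

The repeated-measures ANOVA (2 or 3 within-subject two-level factors)
tests each effect against its own effect-by-subject interaction,
implemented via per-subject ±1 contrast scores (F = squared paired t,
df = (1, n−1)); for all-two-level designs this is algebraically identical
to the full sum-of-squares partition, which an independent
inclusion-exclusion oracle verifies to 1e−8 in the tests.
Greenhouse–Geisser correction is unnecessary: with two levels per factor
sphericity holds trivially.

## Simulation-based signatures and what they show

Generative simulation (choices sampled from the model's own softmax,
outcomes drawn from the task) at the group-mean parameters reproduces the
qualitative dissociations: ABSOLUTE underperforms in punishment/partial
relative to reward/partial (reduced sampling of the counterfactual
option), RELATIVE is symmetric across valence; RELATIVE's final
complete-context values invert (L25 positive, G25 negative) and its
context values resolve better with complete than partial feedback, so the
transfer test shows L25-complete preferred to G25-complete, while ABSOLUTE
preserves the expected-value ordering.

Two simulation modes exist: every agent at the group-mean parameter vector
(used for the acceptance quantities), or per-agent parameters drawn from
truncated normals around the group means with s.d. = s.e.m.·√28 (the
cohort size behind the published standard errors). The group-mean mode is
more deterministic than a real heterogeneous cohort replayed
one-step-ahead: performance is concave in β, so a cohort sharing the mean
β outperforms the average subject of a β distribution with that mean.
Generative rates at the group means therefore sit a few points above the
published model-derived rates, which were computed from real subjects'
histories with individual best parameters; the individual-parameter mode
lands closer. This is a property of the simulation conditions, not of the
learning-rule implementation, which is verified against hand-computed
updates, an independent brute-force simulator and the exact reduction
property.

What passing synthetic tests do **not** show: the generator emulates the
task contingencies, not human behaviour — there are no misses, no reaction
times, no drift in attention or strategy, and parameter heterogeneity is a
parametric stand-in for the empirical distribution. Conclusions about real
cohorts require refitting real trial tables (the documented CSV schema).

## Problem sizes and numerical defaults

Defaults keep every computation comfortably on one CPU: 1,000 synthetic
subjects for group-mean simulation summaries (Monte-Carlo s.e. on a rate
≈ 0.002), 28 subjects × 384 trials for recovery studies, 200 cohorts for
sign-signature rates, 20 optimizer starts per fit (5–8 in recovery tests,
which is sufficient there because simulated data are well-behaved), 10⁶
Dirichlet samples for XP. The pipeline default (16 subjects, 8 starts)
runs in a few minutes; all stages are seeded and byte-reproducible.

## Known limitations

- Valence-specific learning rates, actor–critic and advantage-learning
  variants are not implemented.
- Hierarchical (empirical-Bayes) fitting across subjects is out of scope;
  fits are independent per subject.
- The BMS scheme is the standard variational formulation; protected
  exceedance probability is not computed.
- The transfer-test β is the learning-test β (no re-optimization).
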