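# Methods

## The decision problem

`carebandit` simulates the allocation of AI care-call programs to older
adults living alone and asks how much personalization is worth. Each
interaction step, one simulated user arrives, one care program (an *arm*) is
assigned, and one outcome is realized. Programs are the full factorial of
four attributes — content (check-in, health information, intervention),
frequency (low/high), duration (short/long), voice (A/B) — 24 arms by
default. Four allocation strategies are compared:

1. **Systematic (cyclic)** — arms in fixed rotation, ignoring the user.
2. **Single best** — everyone receives the arm with the highest
   population-average expected benefit, computed from the true model (the
   limit of an infinitely large randomized trial without effect
   modification).
3. **Oracle** — the true model's best arm for each individual user; the
   upper bound of personalization, with zero regret by construction.
4. **Linear Thompson Sampling (TS)** — a contextual bandit that learns the
   reward structure online from realized outcomes.

## Populations

Users are binary feature vectors over nine demographic/health indicators:
old-old age (≥75), female sex, rural residence, economic instability,
multimorbidity, functional difficulty, loneliness, impaired cognition, and
living alone. Two population modes are provided:

* **CHS mode** (survey-like, n = 72,812): features drawn independently with
  fixed marginals (old-old 47%, female 58.4%, rural 59%, lonely 6.4%;
  features without published margins default to 50%). Independence reflects
  that only aggregate distributions are available for such surveys.
* **AI-Call mode** (intervention-cohort-like, n = 1196): profiles drawn from
  a *synthetic joint fixture* standing in for a cohort table that cannot be
  distributed. The fixture is built by a Gaussian copula (latent correlation
  0.2 between all feature pairs by default), collapsed to distinct profiles,
  then raked (iterative proportional fitting) so every marginal matches its
  target (old-old 79.8%, female 77.2%, rural 71.4%, lonely 11.4%) to within
  1e-9. The joint structure is therefore plausible but synthetic; only the
  margins are calibrated.

Users are drawn i.i.d. with replacement each step — a 3000-step horizon
exceeds the AI-Call pool size, so a without-replacement "shuffle" is not
meaningful at this scale.

## Context encoding

Each (user, arm) pair is encoded as
`x = [1 | 9 user features | 5 arm dummies | 7 interactions]`, d = 22.
Arm dummies are reference-cell coded against check-in/low/short/voice-A, so
the intercept is the reference program's baseline. The seven interaction
terms encode who benefits from what, identically in every outcome model:

| user feature | program attribute | benefit direction |
|---|---|---|
| female | long duration | + |
| functional difficulty | long duration | + |
| rural | high frequency | + |
| old-old | check-in content | + |
| impaired cognition | check-in content | + |
| lonely | intervention content | − |
| multimorbidity | health-information content | + |

The check-in preferences use the check-in *indicator* (1 − the two content
dummies) as the arm factor, which keeps a preference for the reference
program expressible as a single term and the dimension at 22.

## Ground-truth reward models

Three outcomes: call success (Bernoulli, logistic mean, higher better),
PHQ-2 (integers 0–6, lower better), SRH (integers 1–5, higher better). The
ordinal outcomes use a linear mean clipped to the scale, realized by
probabilistic rounding (⌈y⌉ with probability frac(y)), which is
mean-preserving, so the clipped linear prediction *is* the exact expectation
of the integer outcome.

Coefficients on the outcome's natural scale:

* **AI-Call mode** (sign-constrained): each main effect is
  (benefit sign) × (outcome orientation) × (constant magnitude). The benefit
  direction table treats every health burden (old-old age, economic
  instability, multimorbidity, functional difficulty, loneliness, impaired
  cognition, living alone) as worsening all outcomes, female sex as mildly
  improving engagement, rural residence as a barrier; among program
  attributes, health-information content and high frequency help on average,
  intervention content and long duration cost engagement, voice is neutral.
  Magnitudes: 0.5 (logit scale) / 0.3 (outcome scale) for mains, 1.0 / 0.5
  for interactions. The linear interaction magnitude is chosen so predictions
  stay in the interior of the bounded 0–6 / 1–5 scales for typical profiles;
  larger values saturate the scales, which collapses the personalization
  margin (the population-best arm then attains the bound for almost
  everyone) and distorts the policy comparison the study is about.
  Intercepts (−0.25 logit; 2.8 PHQ-2; 3.0 SRH) put the systematic policy's
  mean near the study's baseline operating points.
* **CHS mode** (random): main effects drawn once, seeded, i.i.d.
  Uniform(−0.5, 0.5); the seven interactions keep their fixed directions and
  default magnitudes. The intercept is calibrated so that the mean linear
  predictor under systematic allocation equals a fixed baseline anchor
  (success rate 58.72%; PHQ-2 2.73; SRH 3.18). Without this centering the
  operating point of the logistic model wanders with the random draw,
  sometimes into saturation where the comparison degenerates.

The ground-truth coefficients and the copula fixture use their own fixed
seeds (default 0), configurable separately from the simulation master seed:
the data-generating mechanism is part of the scenario definition, so
different master seeds re-randomize the runs, not the science.

The bandit maximizes a common oriented reward in [0, 1]: call success
unchanged, SRH mapped by (v−1)/4, PHQ-2 reversed by (6−v)/6.

## Thompson Sampling

A single Bayesian linear model over the joint context is shared by all arms
(the arm dummies and interactions carry the arm-specific structure), rather
than disjoint per-arm models — matching a setting where one outcome model
links context to reward. State: precision B = λI + Σxxᵀ, response f = Σrx,
posterior mean μ = B⁻¹f. Each decision draws one θ ~ N(μ, v²B⁻¹) (a single
draw shared across arm scoring) and plays argmax xᵀθ; after observing the
realized oriented reward the state absorbs a rank-one update
(Sherman–Morrison on B⁻¹, with B kept alongside). TS observes the realized
rounded integer outcome (oriented), not the latent linear value.

Hyperparameters: ridge λ = 1. The posterior noise scale v defaults per
outcome family, matched to the oriented observation noise: v = 0.5 for
Bernoulli rewards (sd up to 0.5) and v = 0.15 for the rounded ordinal
outcomes, whose oriented rounding noise has sd ≲ 0.1. A single v = 0.5
grossly over-explores the low-noise outcomes and its exploration cost then
exceeds the entire personalization margin over a 3000-step horizon.

## Experiment design and regret

Default study: 2 population modes × 3 outcomes × 4 policies × 100
replications × 3000 interactions. Within a replication all policies see the
same user sequence and the same outcome-noise stream (common random
numbers, realized as shared per-step uniforms used as Bernoulli/rounding
thresholds); TS has a private stream for posterior draws. All streams derive
from the master seed via `numpy.random.SeedSequence` with small integer
stream tags, so runs are bit-reproducible. TS starts fresh each replication.

Instantaneous regret is the *noiseless expected* oriented reward of the
oracle arm minus that of the chosen arm (standard bandit regret; lower
variance than realized-outcome regret, identical in expectation). Static
policies accumulate regret linearly; the oracle's is identically zero; TS's
cumulative regret tapers as the posterior concentrates.

Because the profile space is finite (≤2⁹ profiles × 24 arms), the engine
precomputes all context encodings and expected rewards once per scenario;
only the TS loop is sequential. The full default study runs in about a
minute on one CPU.

## Evaluation

* **Summary table**: mean (SD over replications) of the per-run average
  outcome, per policy × outcome × population; call success as a percentage.
* **Statistical comparisons** (systematic vs TS): chi-square without
  continuity correction on pooled success/failure counts; two-sided
  Mann-Whitney U (tie-corrected normal approximation) on pooled per-call
  ordinal scores. Per-call pooling across replications is the default unit
  of analysis; per-run means are available via the summary frame. No
  multiplicity adjustment is applied.
* **Figures**: per-replication outcome distributions by policy, and average
  cumulative-regret curves, one panel per population × outcome.

## What the synthetic data does and does not show

The generator reproduces published *marginal* population structure and a
domain-plausible interaction structure; it does not reproduce real joint
dependence (the AI-Call fixture's copula correlation is an assumption), real
effect sizes (coefficient magnitudes are design choices — the source tables
publish directions, not magnitudes), nonstationarity, dropout, or any
feedback of interventions on future user state. Passing tests therefore
demonstrate the *mechanics* of the allocation policies — regret structure,
learning, ordering of policies when heterogeneous effects exist — not the
clinical effect sizes a deployment would achieve.

## Numerical choices and edge cases

* Linear predictions are clipped to the scale bounds before rounding;
  probabilistic rounding then cannot exceed the bounds.
* All argmax tie-breaks (every policy) resolve to the lowest arm id.
* The fixture raking loop enforces marginals to 1e-9 and fails loudly if a
  feature degenerates (all-0/all-1 in the copula sample) or raking cannot
  converge; remedies are a larger copula sample or weaker correlation.
* `B⁻¹` is symmetrized before each Cholesky; with λ = 1 and binary bounded
  contexts the precision matrix stays comfortably positive definite over
  3000 rank-one updates (inverse drift ~1e-8, checked in tests).
* Population-average arm values sum the exact per-profile expectations over
  the profile distribution — the logistic mean is nonlinear, so plugging in
  mean features would be wrong.

## Known limitations

* Call frequency is an arm attribute inside the per-call reward; it does not
  change how many interactions a user receives.
* Binary call-success rewards are fed to the Gaussian linear TS machinery
  directly (no logistic posterior); this is the standard linear-TS treatment
  and is slightly misspecified for Bernoulli noise.
* The nine-feature schema includes five features without published margins;
  they default to 50% and are configurable.
* Exact published headline values (e.g., specific success percentages)
  depend on unpublished coefficient magnitudes; this package reproduces the
  qualitative structure — policy ordering, regret shapes, significance — and
  operating points of the same order, not those exact numbers.
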