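# Methods

## Optimal frontier

The constrained problem — maximize average reward `V^π` subject to
`I(S;A) ≤ C` over row-stochastic π — is solved through its Lagrangian
`β·V − I`.  For tabular state/action spaces the optimum satisfies
`π*(a|s) ∝ exp[β·Q(s,a) + log P*(a)]` with `P*` the state-averaged
marginal, and alternating these two updates (Blahut-Arimoto) converges to
the global optimum.  Numerical choices:

- Natural logarithms throughout; complexities are in nats.
- Marginal initialized uniform (the β=0 fixed point); convergence when the
  marginal changes by less than 1e-10 in max-norm; iteration cap 100,000.
  The large cap matters at small β whenever some action is strictly
  dominated (set sizes not divisible by 3): its marginal mass decays at
  rate ≈ (1 − β/3) per iteration, so β ~ 1e-3 needs tens of thousands of
  iterations.
- 0·log 0 is 0; probabilities are floored at 1e-16 inside logarithms only.
- Default β grid: 0 plus 200 geometrically spaced points in [1e-3, 50] —
  geometric spacing resolves the low-complexity knee where subjects lie.
- Curve sweeps warm-start each solve from the previous marginal remixed
  with 10% uniform mass.  The remixing is load-bearing: a pure warm start
  traps actions suppressed at low β at the log floor, and they can never
  re-enter the support when β grows (the curve then kinks and loses
  concavity).
- `beta_for_capacity` and `optimal_reward_at` interpolate the (complexity,
  β) and (complexity, reward) graphs piecewise-linearly.  A consequence
  worth knowing: the linear chord *under*-estimates the strictly concave
  frontier between grid points by up to ~1e-5 at the default grid, so
  exact policies evaluated off-grid can exceed the interpolated frontier
  by more than round-off.  Dominance checks therefore use a 1e-4 margin
  off-grid.
- The frontier depends on the multiset of correct actions, not only the
  set size: a block whose stimuli share one rewarded action has frontier
  reward 1 at zero complexity.  Frontier comparisons for simulated
  policies use the block's own assignment; the per-set-size curves used in
  the cohort analysis use the balanced assignment, matching how the
  published frontiers are drawn.

## Empirical complexity

A subject's complexity per set size is estimated from the pooled
(stimulus, action) count table of all same-set-size blocks (stimuli are
unique across blocks, so pooled rows are distinct states; the state prior
is the empirical stimulus frequency).  The estimator is the exact
posterior mean of the mutual information under a symmetric Dirichlet prior
with concentration α = 0.1 — with `a_ij = n_ij + α` and `A = Σ a_ij`,

    E[I|n] = Σ_ij (a_ij/A)·[ψ(a_ij+1) − ψ(a_i+ +1) − ψ(a_+j +1) + ψ(A+1)].

Small α suits sparse joints (one rewarded action per state); at 50 trials
its absolute error is smaller than the plug-in estimate's upward bias, and
the two converge as counts grow.  Only the posterior mean is used; no
credible intervals.

## Process models

The cost-sensitive actor-critic holds per-block actor weights θ (zeroed at
block start — stimuli are new), a per-block critic V̂ (zeroed), a
subject-level marginal P(a) (initialized uniform, persists across blocks,
floored at 1e-8 and renormalized), and an inverse temperature β.  Policy:
`π(a|s) ∝ exp[β·θ_sa + log P(a)]`.  Per trial, with the *pre-update* π:

    cost  = log[π(a|s)/P(a)]
    δ     = β·r − cost − V̂(s)          (no_cost variant: δ = β·r − V̂(s))
    θ_sa += (α_θ/t)·δ·(1−π(a|s))·β      (t = within-block trial index)
    V̂(s) += α_V·δ
    P(a')+= α_P·(π(a'|s) − P(a'))       for every a'

The 1/t decay keeps the actor slower than the critic; the running
complexity estimate R is the last realized cost, reset to 0 at block start
(its first-trial value is otherwise undefined).  An optional switch scales
the actor rate additionally by the set size (off by default; the update is
implemented as displayed above).

Adaptive variants replace the fixed β with a per-trial gradient step
toward a capacity C:  Δβ = α_β(C − R)·[θ_sa − Σ_a' θ_sa' π(a'|s)], with
the post-update θ and pre-update π, floored at 0 and capped at 50 (the θ
step scales with β², an unguarded positive feedback that otherwise
overflows for large α_β).  β restarts at β0 with each block, re-adapting
to that block's set size.  Two properties of this update deserve honesty:
under on-policy simulation the bracket is a zero-mean score, so the C term
contributes no drift — the systematic component is −α_β·Cov(R, score) < 0
and the realized complexity does not actually track C; the capacity
becomes informative only when the model is fitted to externally generated
choices, where the score is no longer zero-mean.  Fitted to the synthetic
cohorts and replayed, the learned β averages slightly lower during
set-size-6 blocks than set-size-2 blocks (mean difference ≈ −0.05), the
direction and magnitude reported for this class of task; the per-block β
restart is what lets that comparison reflect set size rather than block
order.

The same recursion is the prequential likelihood of observed choices.  A
numba kernel reproduces the Python reference path bit-for-bit (tests
assert agreement to 1e-8 over all four variants).

## Fitting

Bounded estimation per subject: β, β0 ∈ [0,20]; learning rates ∈ [0,1];
C ∈ [0, ln 3] (three actions cap the useful capacity).  The optimizer
screens the objective at the bounds midpoint plus 256 Latin-hypercube
points, polishes the best `restarts` candidates (default 6) with L-BFGS-B,
always also polishes a near-null start (the uniform-choice baseline), and
breaks numerical ties toward the minimal-parameter vector.  The optimized
objective is the negative log-likelihood plus a weak ridge — at most 0.2
nats per parameter, reached only at the upper bound — which resolves the
likelihood-flat directions left by degenerate responding: a chance-level
subject otherwise admits corner optima (e.g. α_P at 1) that win on
fractions of a nat of noise and are meaningless as estimates.  Reported
nll and BIC (= 2·nll + k·ln n_trials, n_trials the subject's trial count)
are the pure likelihood at the chosen parameters.  Same-data refits agree
to ~1e-7, so estimates are reproducible; the attained penalized objective
is monotone in the number of restarts.

Parameter recovery follows the self-consistent design: fit every subject,
simulate each fitted model *on the same stimuli that subject saw* (the
task design is reconstructed from the trial log), refit, and correlate
generating with recovered values per parameter (Pearson).  On the default
85-subject synthetic cohorts the marginal-learning-rate correlation is
~0.9 and the critic rate ~0.5-0.65; β and α_θ carry the noise of a shared
likelihood ridge (policy logits scale like α_θ·β³ during short
criterion-length blocks, so distant (β, α_θ) pairs produce near-identical
behavior) and correlate ~0.2-0.5 depending on the realization.  Recovery
from broad uniform parameter draws is markedly worse for β and α_θ for
the same reason, which is why the anchored design is the informative one.

Model comparison uses random-effects Bayesian model selection on
log-evidences approximated as −BIC/2: a variational Dirichlet posterior
over population model frequencies, exceedance probabilities from 1e6
Dirichlet draws (seeded), the Bayes omnibus risk BOR from the variational
free energy against the equal-frequency null, and the protected
exceedance probability PXP = EP·(1−BOR) + BOR/M.  On cohorts generated by
the fixed model the generating model is identified decisively
(PXP ≈ 1 against the adaptive variants; the no-cost ablation is
disfavored, sharply so at larger cohort sizes).  Cohorts generated by the
*adaptive* variants are largely not identifiable on this design: the
fixed model fits the same data within a few nats per subject, below the
BIC cost of the extra parameters — the task yields nearly indistinguishable
behavior across these model classes, so their recovery stays at
PXP well under 0.9 even with the adaptation learning rate drawn from its
behaviorally expressed range (0.5-1.0).

## Synthetic data generator

The generator emulates the set-size experiment: 13 blocks per subject with
set-size multiset {2:3, 3:3, 4:3, 5:2, 6:2} (the original distribution
across blocks is not published; this covers every size), globally unique
stimuli, a random stimulus-to-correct-action map, and shuffled round-robin
scheduling with online retirement (≥9 presentations and 4-of-last-5
correct, or 15 presentations).  Block length is therefore
performance-dependent, as in the experiment.  Cohorts: 36 control-like and
49 patient-like subjects; generating parameters drawn uniformly with the
patient-like group lower in β (1.5-5 vs 3-8) and higher in actor learning
rate (0.15-0.5 vs 0.05-0.3), identical critic-rate (0.1-0.6) and
marginal-rate (0-0.05, concentrated near zero) distributions.  These
magnitudes are design choices; only the directions of the group
differences are anchored in the literature.

What the generator does not emulate: reaction times, demographics, symptom
scores, engagement lapses, and any within-subject parameter drift.
Passing the cohort-contrast tests therefore shows the pipeline recovers
the directional structure its own generator plants — lower patient-like
complexity, higher patient-like bias, negative bias-complexity
correlation, a shared empirical curve, and set-size-ordered learning
curves — not that real cohorts would produce the same effect sizes.

## Analysis conventions

Empirical curves are 2nd-order polynomials of reward on complexity.  The
joint-vs-independent comparison scores a shared quadratic (3 mean
parameters) against per-group quadratics (6) by Gaussian-residual BIC;
positive ΔBIC favors the shared curve.  Bias is the interpolated frontier
reward at the point's complexity minus the empirical reward; complexities
beyond the frontier maximum clamp to the terminal reward, and bias may be
negative for points estimated above the frontier.  The group ANOVA is a
fixed-effects two-way decomposition (group × set size, type-II sums of
squares) on per-subject per-set-size aggregates, cross-checked against an
independent implementation.  Learning curves average reward by the
within-block presentation index of each stimulus.

## Known limitations

- β and α_θ are weakly identified from single-session data; point
  estimates scatter along a likelihood ridge and their recovery
  correlations are realization-dependent.
- The adaptive variants' capacity parameter has almost no influence on
  simulated behavior (see above), and the design cannot discriminate them
  from the fixed model.
- The generator's parameter magnitudes are plausible but not calibrated to
  any dataset; inferential statistics computed on synthetic cohorts do not
  estimate the published cohort statistics.
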