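# Methods

## The task

The heist task is a two-stage planning problem. On each trial one of two
doors (dark/light) is presented in one of four contexts, each cued by a
coloured gem. The dark door leads to a high-stakes "heist" state with
probability `p` and to a neutral state with probability `1 - p`; the light
door has the complementary probabilities. `p` switches between 0.2 and 0.8
with hazard 0.1 per trial. A per-trial valence cue announces whether the
heist state pays +1 (gain) or -1 (loss); the neutral state always pays 0, so
the optimal policy is to approach the heist state on gain trials and avoid
it on loss trials, which requires tracking `p` but not state values.
Contexts come in pairs: in *dependent* blocks the pair shares one transition
schedule (yoked); in *independent* blocks each context has its own. The fMRI
design interleaves the two contexts of a block randomly (16 + 16 trials per
32-trial block, 24 forced / 8 free, 5 sessions of one block per condition,
320 trials); the pilot design has 8 blocks of 60 free-choice trials.

Generator choices the design leaves open: the initial schedule level is
drawn uniformly from {0.2, 0.8}; context interleaving is a random
permutation with exactly equal counts; the door presented on forced trials
is a fair coin, independent of `p` (decorrelating choice from belief is the
point of forced trials); the generator produces no missed trials, but missed
trials are supported as a choice flag and ingestion of external data drops
them.

## The dual learner

The agent holds a context-specific estimate of `p` per context and a
context-independent estimate per condition (shared by the condition's two
contexts). All estimates start at 0.5 and are never reset. At choice time

    p_hat = w_eff * p_independent + (1 - w_eff) * p_specific[context]

with `w_eff = w` in the dependent condition and, under the *flexible*
variant, `1 - w` in the independent condition (the *fixed* variant uses `w`
everywhere). Door values are `q_dark = r * p_hat`, `q_light = r * (1 -
p_hat)` with `r = ±1` for gain/loss, and the dark door is chosen with
probability `1 / (1 + exp(beta * (q_light - q_dark)))`. After observing the
transition, the state prediction error `delta = x - p_hat` (x = 1 for
dark→heist or light→neutral) updates both learners:

    p_independent += w_eff * alpha * delta
    p_specific    += (1 - w_eff) * alpha * delta

each clamped to [0, 1] immediately after its own update. Beliefs update on
every non-missed trial (forced or free); only free, non-missed trials enter
the choice likelihood. Missed trials consume no estimate and trigger no
update. `p_independent` is kept per condition pair and carries across the
blocks of that condition, isolated behind the `BeliefState` type.

Parameters: `alpha` (learning rate, [0, 1]), `beta` (softmax inverse
temperature, ≥ 0), `w` (mixing weight, [0, 1]).

## Hierarchical fitting

Subject parameters are random effects from a diagonal Gaussian over
transformed parameters (logit `alpha`, log `beta`, logit `w`).
Expectation-maximization alternates per-subject MAP fits (L-BFGS-B on the
negative log posterior, evaluated by a compiled replica of the update
equations) with moment updates of the group mean and variance that include
the Laplace posterior-covariance correction. Per-subject evidence is the
Laplace approximation `log p(data) ≈ -obj(theta*) + (3/2) log 2π - ½ log det
H` with `H` the central-finite-difference Hessian (step 1e-4), symmetrised
and eigenvalue-floored at 1e-6.

Numerical choices that matter:

- Transformed parameters are optimised inside a [-8, 8] box
  (`sigmoid(8) ≈ 0.99967`, `exp(8) ≈ 2981`); beyond this the data cannot
  distinguish values and unbounded MAPs destabilise the group moments.
- Group variances are floored at 1e-6 (prior-collapse guard) and capped at
  16: a diagonal prior wider than the box is already flat, and without the
  cap weakly identified cohorts enter a feedback loop (flat prior → huge
  posterior variances → flatter prior).
- The flexible model's likelihood is nearly symmetric under `w ↔ 1 - w`
  whenever the cross-context coupling (of order `w_eff² alpha`) is weak, so
  per-subject posteriors can be bimodal. `subject_map` therefore always
  probes the mirrored mode (sign-flipped logit `w`) and keeps the better
  posterior.
- EM stops when the summed evidence changes by < tol or the prior moments
  move by < 1e-4; restarts (prior mean + seeded Gaussian perturbations) are
  used on the first sweep, warm starts plus one fresh start afterwards.

Subject-level LOOcv refits the group prior without each subject
(warm-started from the full-cohort fit, keeping the procedure independent of
subject ordering) and scores the held-out subject's negative Laplace
evidence; lower is better. Models are compared with a two-sided paired
t-test plus per-subject win counts. Absolute score levels depend on Laplace
constants and transform conventions; score *differences* between models are
the meaningful quantity.

### Synthetic cohorts (study conditions)

Recovery analyses simulate cohorts of 29 subjects × 320 trials from group
means `alpha = 0.56`, `beta = 1.59`, `w = 0.85` (flexible) or
`alpha = 0.65`, `beta = 1.80`, `w = 0.61` (fixed). Group SDs in transformed
space are (1.0, 0.5, 1.5) for (logit alpha, log beta, logit w) — the scale
of between-subject spread hierarchical fits themselves estimate on such
cohorts, giving a 95% subject range of roughly alpha 0.15–0.90, beta
0.6–4.2, w 0.23–0.99. Reading SDs directly off reported confidence
intervals (SD = √n · SEM) would instead give logit-w SD ≈ 3.1, a population
in which a quarter of subjects share deterministically (w > 0.99); that
reading double-counts per-subject estimation noise and was not used.

Known limitation: with 80 free-choice trials per subject, per-subject `w` is
weakly identified (the `w ↔ 1 - w` near-symmetry above), so rank recovery of
subject-level `w` fluctuates around Spearman ρ ≈ 0.5 across cohort draws
even though group-mean recovery is stable (error ≲ 0.1). Posterior-mean
estimation via two-mode importance sampling was evaluated and did not
improve rank recovery.

## Behavioural statistics

Trial-history analysis recodes choices into a valence-free frame: evidence
from trial `t - n` is +1 if it suggested the dark door reaches the heist
state (dark→heist or light→neutral observed), -1 otherwise, sign-flipped
when the current trial is a loss trial, and routed to a Same or Other column
by context match. Lags are set to 0 when they cross a block boundary
(contexts and schedules change at block breaks) or land on a missed trial.
`differential_evidence` is the mean of the five Same columns minus the mean
of the five Other columns; the key statistic is the `differential_evidence ×
condition` interaction (condition coded +1 dependent / -1 independent) in a
logistic regression of choice.

The regression backend is pluggable: the default is a logistic GLM with
subject-clustered robust standard errors; a Bayesian random-intercept GLMM
and an L2-penalised (separation-robust) solver are available. The original
fully crossed 11-term random-slopes GLMM is frequently singular at n = 29
and its standard errors are not part of the contract — coefficient patterns
are, and the cluster-robust backend reproduces them at a fraction of the
cost (hundreds of fits are needed for the simulation analyses).

The agent-based permutation null simulates groups of 29 fixed-model agents
whose (alpha, beta) are resampled from a fitted pool and whose `w` is drawn
uniformly on (0, 1) and cannot reverse between conditions; the interaction
coefficient is collected per group, and an observed estimate is compared
against the 2.5–97.5 percentile range with an add-one two-sided empirical p.

Consistency analysis: each free trial with a valid predecessor in the same
block is a *repeat* trial if the previous terminal state is desirable again
(prev heist & gain, or prev neutral & loss) and a *switch* trial otherwise;
a choice is consistent if it repeats (repeat trials) or switches (switch
trials) the previous door. Trials split by the previous outcome's valence
(positive: +1 on gain / 0 on loss; negative: -1 on loss / 0 on gain); the
per-valence score averages the repeat and switch category percentages, and
`valence_effect` is positive minus negative. Note that symmetric learners
already show a positive valence effect (~10 points at the pilot design):
previous successes are exactly the trials on which the observed transition
confirmed the agent's beliefs, so evidence-following looks more consistent
after positive outcomes. Asymmetric (positive-only) updating adds to this
baseline; simulation claims about valence asymmetry should therefore be
comparative, not absolute.

## Synthetic multivoxel patterns

Each (context, bin) cell has a voxel-length prototype drawn i.i.d. standard
normal; *shared* conditions copy one prototype set across the condition's
two contexts, *separate* conditions draw per context. A trial's pattern is
its cell prototype plus i.i.d. Gaussian noise (default sd 4, chosen so that
single-condition RSA effects are moderate rather than saturated at 200
voxels and ~20 trials per cell) plus a per-run offset (sd 0.5) that makes
cross-run cross-validation non-trivial. Bins are probability bins of
p(heist | door presented) (door presentation) or the four choice×state
combinations (outcome presentation). Not modelled, hence not probed by any
passing test: hemodynamics, spatial autocorrelation, scanner drift,
voxel-specific noise levels, and any systematic relation between belief
dynamics and pattern amplitude. Passing RSA/encoding checks show the
*statistics* recover planted structure, not that real BOLD has it.

## RSA

Per context, bin-mean patterns are correlated across contexts giving a
non-symmetric 4×4 matrix (all 12 off-diagonal cells are used, not a
triangle); correlations are clipped at |r| ≤ 1 - 1e-6, Fisher-z transformed,
and summarised as mean(4 diagonal cells) - mean(12 off-diagonal cells). The
condition × diagonal interaction is a paired t-test on per-subject
differences. Probability bins are per-subject quartiles (ties to the lower
bin) or fixed edges 0–.25/.26–.50/.51–.75/.76–1. Cross-run variants compute
bin means per run and correlate only across run pairs i ≠ j, averaging the
Fisher-z matrices; run pairs with an empty cell are dropped with a warning.
The temporal-proximity control computes the mean cross-context temporal
distance of same-bin minus different-bin trial pairs and correlates it with
the RSA difference across subjects. One mild, realistic artefact of the
generator: run offsets plus belief-driven bin occupancy leave a small
positive on-off difference (~0.01 Fisher-z) even under a separate code —
the kind of temporal confound the proximity control exists to flag.

## Encoding model

Model-derived probabilities are converted to log-odds, clipped to [-2, 2]
and assigned to n equal-width bins (n = 1..10); the design is one-hot or a
unit-sum Gaussian tuning curve over bins (default width: one bin). Weights
`W` (voxels × bins) are ridge-stabilised least squares of the design onto
one (context, run)'s trials. Decoding inverts the model generatively: bin
j's score is the Gaussian log-likelihood of the test pattern under the
template `W b_j`, with the df-corrected training residual variance; the
softmax over scores is the decoded distribution, scored by mean
cross-entropy against true bins. This decoder is calibrated at chance —
uninformative weights give near-equal templates, a near-uniform decoded
distribution, and loss ln(n) — which a raw least-squares score inversion is
not (pseudo-inverse scores do not shrink when the weights are noise). The
flip side is honest overconfidence under misspecification: with a *separate*
code, cross-gem templates are confidently wrong and the independent
condition's loss sits well above ln(n) rather than at it. The
generalization contrast trains on each (context, run), tests on the paired
context in other runs, and compares condition means with a paired t-test
per n.

Under the 4-level generative code, the dependent-vs-independent loss
difference is reliable for every n ≥ 2, not only n ≥ 4: an encoding model
whose bins lump generative levels still transfers a shared code above
chance. The real-data observation that the effect needed more than 3 bins
does not emerge from this generator and likely reflects properties of real
BOLD codes that the prototype generator does not emulate.

## Problem sizes

The test suite and the acceptance script regenerate everything from seeds:
parameter recovery uses one 29-subject cohort; model recovery uses 20
cohorts of 6–8 subjects per generator with shortened LOOcv settings
(tolerance 1e-2, ≤ 10 EM iterations, 1 restart); cohort simulations use
20–30 groups of 29 agents; the permutation null uses 100 groups (scaled
down from 500); RSA and encoding use 29 subjects × 200 voxels.
These sizes are the package's defaults for desk-scale verification; all are
arguments, so larger replications only cost time.
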