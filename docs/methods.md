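# Methods

## The task

Two counterbalanced blocks — *approach* (collect a mushroom or do nothing)
and *withdrawal* (throw it away or do nothing) — each consisting of

1. **Instrumental training**, 60 trials over 6 stimuli (3 "good": go is
   correct; 3 "bad": nogo is correct). Every choice is followed by ±20
   cents. Under *deterministic* feedback the correct action always wins;
   under *probabilistic* feedback it wins with probability 0.7 and the
   incorrect action with probability 0.3.
2. **Pavlovian conditioning**: five compound stimuli worth +100, +10, 0,
   −10, −100 cents, each shown 20 times and followed deterministically by
   its outcome. Every fifth trial of the stage is a *query* trial — a
   forced choice between two Pavlovian stimuli with no feedback — giving
   125 Pavlovian-stage trials per block.
3. **Pavlovian–instrumental transfer (PIT)**, 100 trials per block: the
   instrumental stimuli reappear on a Pavlovian background, in extinction.

Money is represented as integer cents. The design label `correct_action`
travels with each trial for descriptive curves only; likelihood code never
sees it.

## The model family

On every choice trial the go/nogo decision is a softmax over additive
action weights

    W(go)   = Q(s, go) + b_block  [ + pi(pav, block) + xi(s) on PIT trials ]
    W(nogo) = Q(s, nogo)

with a Rescorla–Wagner update of the chosen pair only, on outcome-bearing
trials:

    Q <- Q + eps * (rho * r − Q),   r = +1 reward / −1 punishment.

`rho` converts a unit reinforcement into effective value (`rho_rew` on
rewards, `rho_pun` on punishments where split), `b` is a block-specific
static go bias, and the ten `pi` weights — one per Pavlovian stimulus per
block, freely inferred — carry the Pavlovian controller's vote for go. The
two controllers superpose additively inside the softmax; no interaction
terms. Q is initialised at zero and frozen during PIT (no outcomes → no
updates), except:

* model 9 (*extinction*): effective PIT-stage values are `Q_end * gamma**k`
  on the k-th PIT trial of the block (k is 1-based; the decay convention is
  a package choice — only "decay on each trial" is prescribed);
* model 10 (*generalization noise*): a fixed per-stimulus offset `xi[s]`,
  one of 12 per subject, is added to the go weight during PIT; all offsets
  share a single group-level mean and variance.

Models 1–7 are fitted to instrumental trials only; 8–10 to instrumental and
PIT trials jointly. Nesting is exact (e.g. model 8 = model 10 with all
`xi = 0` = model 9 with `gamma = 1`) and is verified to machine precision
in the test suite. Learning rates and the decay live in (0, 1) and are
logistic-transformed for inference; sensitivities, biases, transfer weights
and offsets are unconstrained. Only the chosen action's Q is updated; a
zero-sensitivity punishment still lowers a positive Q toward zero, so
punishment neglect does not make punishments inert.

Likelihood evaluation and its gradient are numba-compiled; the gradient is
exact, propagated analytically through the update recursion and the
PIT-stage decay/offset terms, and is checked against central finite
differences at 1e−5 relative tolerance for all ten models.

## Hierarchical fitting

Per-subject parameters get a diagonal Gaussian prior in inference space.
Fitting is empirical-Bayes MAP-EM:

* **E-step**: quasi-Newton (L-BFGS-B with the analytic gradient) MAP per
  subject; restarts from the prior mean plus prior-scaled jitter (default
  4; warm-started from the previous MAP after the first iteration).
  Laplace posterior variances from the diagonal of the inverse Hessian of
  the negative log posterior (central finite differences of the gradient,
  step 1e−4). Non-positive-curvature coordinates fall back to the prior
  variance and are flagged.
* **M-step**: moment matching — prior mean = mean of MAPs; prior variance =
  mean(MAP² + posterior variance) − mean², floored at 1e−6. Model 10's 12
  offsets are pooled into one shared mean/variance.
* **Objective**: the variational free energy — expected log joint under the
  Laplace posteriors (including the second-order likelihood term
  −v·H/2) plus their entropy. The M-step maximizes it exactly, so the
  trajectory is non-decreasing up to E-step approximation error; stopping
  at |Δ| < 1e−3 or 100 iterations by default. The recovery suites use
  em_tol = 0.02, 80 iterations and 2 restarts: the free energy approaches
  its fixed point geometrically and the group prior is stationary to well
  below its own standard error by then.

Initial prior: zero mean, variance 6.25 per coordinate (weakly informative
on the logistic scale).

## Model comparison

Per-subject likelihoods are integrated over the fitted prior by importance
sampling (default K = 2000 draws, all averaging in log space), and the
group score is

    score = −2 Σ_i log p̂(D_i | prior) + n_hyper · ln(N_choices)

with `n_hyper` counting fitted prior means and variances (model 10's pooled
offsets contribute one pair) and `N_choices` the total in-scope choices.
Lower is better; only Δ-scores between models are meaningful and the score
table reports the integrated likelihood and the penalty separately.

Error bars for the prior means reuse the retained samples: shifting a mean
by δ re-weights each draw by the prior-density ratio; a parabola fitted to
the shifted group log likelihood over ±{0.5, 1, 1.5, 2} seed-SEs (re-scaled
once) yields the SE and a Gaussian 95% interval. Two failure modes are
flagged rather than hidden: a flat likelihood (SE = ∞) and a small
importance-sampling effective sample size (`reliable=False`; with a
27-parameter model and 320-trial likelihoods the ESS is genuinely tiny, and
the intervals undercover — see Limitations).

Absolute fit quality: the per-trial probability of each observed choice
given the past, at the subject's MAP parameters; summarized as a geometric
mean, and a one-sided binomial test of the number of trials on which the
observed action received probability > 0.5 (the "predicted correctly"
construction is a package decision; the geometric mean of a coin-flip agent
is exactly 0.5).

## Synthetic cohorts

Choices are emitted by the same `action_weights` / `choice_probabilities` /
`update_q` code path the likelihood uses, so simulation and inference agree
to machine precision (tested). Per-subject seeds derive from
`SeedSequence((master_seed, subject_index))`; block order alternates across
subjects. Query-trial behaviour uses a lapse model (default 0.02) to mimic
near-ceiling Pavlovian performance; it lies outside all fitted models. For
instrumental-only models, PIT actions are sampled from the frozen
instrumental weights so datasets are always complete.

The documented generating prior (`default_truth_prior`) was calibrated once
to produce the moderate, non-ceiling conditioning the task is designed for:
learning rates spread over ≈0.08–0.65, reward sensitivity ≈2.2 against a
near-zero punishment sensitivity, no approach bias, a bias against
withdrawal go (−0.5), transfer weights ordered by Pavlovian value with
opposite slopes in the two blocks (±0.6 at the extremes), and
generalization noise of unit standard deviation. Recovery suites simulate
under *probabilistic* feedback: deterministic feedback stops producing
prediction errors once behaviour stabilises, leaving the learning rate
nearly unidentified (true-vs-MAP correlation ≈0.2 versus ≈0.6).

What the simulator does **not** emulate: reaction times, mouse kinematics,
off-target (incorrect-location) responses, psychometric covariates, or any
within-subject nonstationarity beyond the models' own dynamics. Passing
recovery tests therefore demonstrates correctness of the inference
machinery under the models' assumptions, not that the models capture all
structure of real behaviour.

## Numerical choices

* Two-action softmax computed as a logistic of the weight difference with
  the stable log1p form; finite for |W| up to the double range.
* Logistic/logit transforms clipped at 1e−15 from the boundaries.
* Importance-sampling Monte-Carlo error by the delta method on the log of
  the mean weight.
* PIT log ratios use a +0.5 continuity correction on both counts;
  stay/switch conditions on the most recent earlier trial with the *same*
  instrumental stimulus; ratios and curves are computed per subject and
  then averaged (spec leaves pooling open).
* Problem sizes: recovery suites use 10 repetitions × 40 subjects × 320
  choice trials (the full task); the acceptance script uses 3 repetitions.

## Known limitations

* **Hyperparameter attenuation.** MAP-EM with Laplace posteriors shrinks
  weakly identified group means: the learning-rate mean is recovered with a
  systematic bias (≈ +0.4 logit under the documented conditions), trading
  off against the reward sensitivity along a likelihood ridge; running EM
  longer moves the fixed point further, so this is a property of the
  estimator, not of convergence. Consequently the generating group means
  fall inside the fitted 95% intervals in only ≈60–65% of cases, and the
  corresponding recovery check is left failing at its nominal strictness.
  Subject-level recovery (correlations) and model recovery are unaffected.
* **Prior-based importance sampling in high dimensions.** With model 10's
  27 parameters the effective sample size per subject is tiny at K = 2000;
  estimates are conservative (biased low) and error bars undercover. The
  implementation surfaces this through the `reliable` flag.
* Diagonal (factorized) group prior only; no full-covariance hierarchy, no
  MCMC, no covariate regression on parameters.
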