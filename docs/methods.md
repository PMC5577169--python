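# Methods

## Model

A single hidden Markov model over per-fixation observation sequences whose
state space is partitioned into two blocks, one per mental-rotation strategy
(LFRR: left fixed, right rotated; RFLR: the converse). The transition matrix
is block-diagonal — zero probability between states of different blocks — so
every state path is confined to one strategy's sub-model. The initial
distribution spans both blocks; its per-block mass is the class prior, and
the posterior strategy probability of a trial is the block's share of the
terminal forward mass (Bayes' rule). Ties in the predicted label go to LFRR.

Emissions factor conditionally on the state:

| component | model | units |
|---|---|---|
| log fixation duration | Gaussian (μ_fd, σ_fd) | log ms |
| log outgoing saccade length | Gaussian (μ_sl, σ_sl) | log px |
| outgoing saccade direction | categorical over SD-1..SD-4 | — |
| AOI occupancy | categorical over L1, L2, R1, R2 — estimated, reported, **not** in the default likelihood | — |

The final fixation of a trial has no outgoing saccade; its density drops the
saccade-length and saccade-direction factors rather than imputing them.

### Why the AOI category is not a default likelihood factor

The AOI chain of a trial is fully determined by its first AOI and its
saccade-direction string (for a fixed source AOI the SD code is a bijection
onto target AOIs). A per-fixation AOI factor therefore double-counts
information already carried by the SD factor, and it does so destructively:
on corpora whose AOI chain is exactly SD-consistent (as the synthetic
generator's is), the four-factor likelihood is globally maximized by hidden
states that track the arm parity of the scanpath (states emitting only
{SD-1, SD-3} versus only {SD-2, SD-4}) rather than the processing states —
we measured a ~12,000-nat advantage for that degenerate solution at 1000
trials per class. With the three-feature density the generating process is
inside the model family and the processing states are identifiable. The
per-state AOI occupancy is still re-estimated from the state
responsibilities on every M-step, so fitted models report the occupancy
rows that parameter tables conventionally show; `include_aoi=True` restores
the four-factor density for data where AOI is informative beyond the SD
stream.

## Training

1. **Labelled Baum–Welch.** Responsibilities of a labelled trial are
   confined to its block, which reduces to independent EM per block; the
   joint initial distribution assigns each block its empirical class
   frequency times the within-block initial distribution. Random restarts
   (default 10) start from seeded perturbations of the pooled moment
   estimates with sticky random transitions; each restart runs a moderate
   number of iterations (default 100, absolute tolerance 1e-3 on the total
   log-likelihood), and the best restart is then polished to a much tighter
   tolerance (default 1e-5, up to 1500 iterations). The polish matters: EM
   creeps near the optimum when emission distributions overlap (the two
   long-duration states differ mainly in their SD rows), and low-occupancy
   states converge last. Starved states (posterior occupancy < 1e-8) are
   re-seeded with a warning. The per-iteration total log-likelihood is
   non-decreasing to within 1e-8.

2. **Discriminative refinement.** Gradient ascent on the conditional
   log-likelihood Σₙ log P(cₙ | Xₙ, λ). All constrained parameters are
   reparameterized (softmax logits for π, the within-block transition rows
   and the categorical emissions; log σ for the Gaussians), so every iterate
   is a valid model. The gradient is the difference between block-restricted
   and full-model expected sufficient statistics from forward–backward,
   pushed through the softmax Jacobian; it is verified against central
   finite differences in the test suite (relative error < 1e-5). Steps are
   accepted only if the objective does not decrease — the step size is
   halved on rejection and gently grown on acceptance — so the recorded
   objective history is monotone. The named "discriminative EM" update
   equations are not pinned down anywhere we could follow; what is pinned
   down, and what this implementation guarantees, is the objective (the
   conditional likelihood) and the contract (monotone accepted steps, valid
   parameters).

Numerical floors: 1e-12 on categorical probabilities (keeps log-space
finite), 1e-3 on σ. Forward passes are scaled per step, so sequences of
10⁴ fixations evaluate without underflow. Viterbi decoding breaks ties
toward the lowest state index.

## Feature coding

Fixations are assigned to the four rectangular-or-polygonal AOIs by
point-in-region containment (inclusive of edges; regions are validated to be
pairwise disjoint, so ties cannot arise). Fixations outside every region are
dropped before saccades are formed — consecutive *retained* fixations define
a saccade — with an optional snap-to-nearest-region alternative within a
pixel threshold. Saccade length is the Euclidean distance between the two
fixations' coordinate points (one x, y per fixation); a data definition that
spans raw gaze samples between fixation onset and the next fixation's end
would need the raw gaze stream, which the fixation-table input does not
carry. Coincident consecutive fixations get a 1-px floor so the log stays
finite. Logs are natural; durations enter in ms and lengths in px before the
transform. The five per-trial aggregates for the baselines (fixation count,
mean/SD duration, mean/SD saccade length) are computed on the untransformed
scales with sample SDs, defined as 0 when fewer than two values exist.

## Synthetic generator

The generator is the generative reading of the fitted model, with defaults
fixed to the published three-state-per-strategy parameter tables:

- initial probabilities (9, 5, 35 / 15, 4, 31)%, concatenated and
  renormalized from their printed 99% total, so the two
  searching-on-one-side states carry a combined 66% of the raw mass;
- per-state duration and saccade-length medians (e.g. 96/170/179 ms and
  37/67/52 px for LFRR) treated as back-transformed log-normal medians with
  a log-space σ of 0.5 — the printed "μ + σ" dispersion notation does not
  determine the log-space scale, so 0.5 (a typical fixation-duration
  log-spread) is the configurable convention;
- the four text-reported transition leave probabilities (0.68/0.60 from the
  encoding state, 0.71/0.78 from the searching state), with the departing
  mass split equally between the two other states and a uniform row for the
  comparison state — the remaining entries are a documented convention, all
  overridable;
- SD rows as printed, with exact zeros floored at 1e-3 and renormalized so
  generated corpora are not degenerate;
- sequence lengths negative-binomial (mean 20, dispersion 5, minimum 1),
  reflecting that small-disparity trials can have only one or two fixations;
- corpus scale 840 trials per strategy over 15 subjects (1680 total) with a
  seeded stratified 80/20 split (1344/336).

Scanpaths are self-consistent: the first AOI is drawn from the first state's
occupancy row, each SD code from the state's SD row, and every subsequent
AOI is the one the SD code implies. Re-coding the emitted raw fixation table
through the feature extractor therefore reproduces the generated AOI and SD
streams exactly (a property test). Consequently the per-state AOI marginals
are emergent rather than forced to the printed occupancy rows, and recovery
experiments target the SD rows, initial probabilities and duration
parameters, not the AOI rows.

Reaction times are intercept + slope × angle + Gaussian noise, truncated at
the 8000 ms response cap; defaults use the published strategy slopes
(13.340 / 11.377 ms per degree), a 1500 ms intercept and 300 ms noise SD.

### What the generator does and does not emulate

It reproduces the fitted model's state structure, the factorial stimulus
design (7 angles × 2 axes × 2 identities × 2 symmetries = 56 conditions) and
the behavioural angle effect. It does not reproduce several properties of
real recordings: per-subject heterogeneity (subject identifiers are assigned
round-robin, not modelled), AOI occupancy as a per-fixation class signal
(see above — in generated data the occupancy difference between strategies
enters only through the first fixation and the SD dynamics), measurement
noise and calibration error, or whatever distributional structure made the
real-data classifiers much more separable than the synthetic ceiling.
Passing recovery tests therefore show the estimator is consistent for its
own model class at realistic sample sizes; they do not certify real-data
accuracy levels.

Two stated acceptance properties do not hold under this generator, and the
corresponding tests are left failing rather than adjusted:

- *SVM above logistic regression.* The five summary features differ between
  the generated classes essentially by a small mean shift, which the linear
  model captures fully; the RBF SVM (C = 1; the kernel and regularization
  are conventions, as no values are reported) has no nonlinear structure to
  exploit and is not reliably better (4/10 seeds at full corpus scale). The
  sequence model beats both baselines in 10/10 seeds.
- *Selecting 3-3 over 2-2.* Fitting 2-2/3-3/4-4 models on a full-scale
  corpus and scoring 8000 fresh trials gives 65.2% / 66.0% / 65.5%: the
  asymptotic gain of the true state count is ~0.8 accuracy points, below
  the level-off rule's own 1-point margin, so the rule correctly prefers
  the smaller model about half the time. Merging two states barely hurts
  two-class discrimination even though it misdescribes the states.

## Evaluation

Stratified k-fold CV (scikit-learn folds), re-shuffled per repeat with
derived seeds; `repeats=1, k=n` reduces to leave-one-out. Confusion matrices
report row-wise (per-actual-strategy), column-wise (per-prediction) and
total accuracies, formatted to 0.1%. State-count selection makes the
level-off idea explicit: the smallest configuration (by total states, then
block imbalance) whose mean validation accuracy is within a margin (default
1 accuracy point) of the grid maximum; enlarging the margin can only select
a smaller or equal model. Majority-vote selection between two
configurations counts participants favouring each and keeps the simpler
model unless a two-sided Wilcoxon signed-rank test is significant at 0.05
*and* the larger model has the better mean. The rank-sum test uses the
exact permutation distribution for tie-free samples up to n = 25 per group
and the tie-corrected normal approximation otherwise. ANOVA on classifier
accuracies is the classical one-way F test; both fold-level and
repeat-level units are available to the caller, and no multiple-testing
correction is applied. The angle-effect slope is ordinary least squares of
RT on angular disparity in degrees.

## Problem sizes

Default experiment scales were chosen once as the smallest sizes at which
each estimate is stable: model recovery uses 1000 trials per class
(matching the identifiability of the low-occupancy comparison state, whose
initial probability is ~5%); the classifier-comparison and state-selection
experiments use 150 trials per class with 2 restarts and shortened EM
schedules, which reproduces the full-scale ordering of the sequence model
versus the baselines; the behavioural experiment uses 15 subjects × 8
trials per angle, giving a slope standard error of ~0.17 ms/degree.

## Known limitations

- The discriminative stage is first-order ascent with a backtracking line
  search; it is reliable but not fast, and a quasi-Newton step would
  converge in fewer evaluations.
- Per-subject random effects, blink handling, and raw-gaze event detection
  are out of scope; inputs are fixation tables.
- The model is time-homogeneous in fixation count; dwell durations beyond
  the per-fixation duration emission (semi-Markov structure) are not
  modelled.
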