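# Methods

## Generative process

Binary sequences are produced block-wise (4 blocks of 380 trials by
default; observers and analyses treat blocks as independent sequences).
Two repetition probabilities θ = [p(1|1), p(2|2)] govern each transition;
the cross transitions are their complements. Stable-period lengths are
geometric with mean 75 trials, truncated at 300 *by resampling* (draws
above the cap are redrawn), which keeps the distribution geometric below
the bound; the per-trial change probability implied by the truncated
distribution is 1/69.5 ≈ 0.0144 rather than 1/75 — visible later in
parameter recovery. At a change point, probabilities are redrawn
uniformly on [0.1, 0.9] under the constraint that the odds ratio
p/(1 − p) changes at least fourfold — on at least one coordinate when
change points are coupled (main task), on the changed coordinate when
they are uncoupled (control task). The first stimulus of a block is
equiprobable.

A frequency-mode generator produces the classic single-statistic task
(one Bernoulli rate with change points), used by the simulation studies.

## Observers

Both observers are Bayesian in the sense that they compute a posterior
over the tracked statistic under their own assumptions; both read out the
probability estimate as the posterior mean of the transition probability
conditioned on the current stimulus, and confidence as the posterior
log-precision −ln Var.

**Flat (leaky-count Beta).** Transition-pair counts decay exponentially:
the pair observed k steps ago weighs e^(−k/ω). Adding pseudo-counts
(0 or 1 per cell; 1 is the Laplace–Bayes prior), each repetition
probability has a Beta posterior. ω = ∞ is perfect conjugate
integration. With zero pseudo-counts the frequency-mode mean is, after a
burn-in of order ω·ln(1/ε) trials, exactly exponential smoothing with
rate 1 − e^(−1/ω) (the delta rule); the equivalence is asserted to 1e−6
in the tests. With zero pseudo-counts and no relevant data the estimate
is reported as 0.5 and the confidence as NaN (flagged undefined,
excluded from analyses).

**Hierarchical (change-point HMM).** θ may be redrawn from a uniform
prior at any observation with fixed probability p_c. The joint
distribution of θ and the data is filtered forward on a uniform midpoint
grid over (0, 1) (default 50 points per dimension; conclusions are
checked to be grid-robust by a 100-vs-200-point convergence test). Each
step mixes the posterior with the re-injection prior (weights 1 − p_c,
p_c), multiplies by the likelihood of the new observation and
renormalizes; computations are in linear space with per-trial
renormalization, which never underflows at these sequence lengths. The
model prior spans all of (0, 1) although generation uses 0.1–0.9: the
observer is generic and subjects were not told the range. The first
stimulus of a block is uninformative about transitions (likelihood ½).

The per-trial read-out is the moments of the *one-step-ahead* posterior
over θ_{t+1} given y_{1:t} — the change mixture applied once more after
filtering — because that is the distribution the next-stimulus question
is about. At p_c = 1 predictions therefore collapse to the prior (0.5),
and at p_c = 0 the observer equals the ω = ∞ flat observer with
Laplace–Bayes prior; both limits are tested, and the filter itself is
verified to 1e−10 against brute-force enumeration over all change-point
configurations on short sequences.

Structural variants: coupled (single 2-D posterior, change points reset
both dimensions jointly), uncoupled (two independent 1-D chains, each
with its own change mixture; only the chain matching the previous
stimulus receives a likelihood), and frequency (single 1-D chain, every
trial informative). An accumulated log-evidence is exposed for optional
structure comparisons.

## Experiment assembly and sequence selection

An experiment concatenates 4 blocks and carries 100 questions: 68 placed
quasi-periodically (gap 15 ± 5 trials, never adjacent to another
question) and 32 placed immediately before and after 16 selected streaks.
A streak is a maximal run of at least 7 identical stimuli starting after
the 15th stimulus of its block. The pre question sits on the last trial
before the streak and the post question on the trial that terminates it,
so both probe the transition from the *non-repeated* stimulus. A streak
is *suspicious* when the coupled hierarchical observer's confidence in
the repeated transition decreases on average across the streak — i.e.
the repetitions are unlikely enough in context to hint at a change.

Selection requires: at least 8 suspicious and 8 non-suspicious streaks
with at least one of each per block; a mean model-confidence drop of at
least 0.5 log-precision units over the sequence's suspicious streaks
(the "sizeable decrease" criterion, applied to the candidate sequence as
a whole rather than to the selected subset, which would select on the
outcome); and a matched subset of 8 + 8 streaks. Because the observers
reset at block boundaries, candidate *blocks* are generated and
evaluated independently and experiments assembled from admissible ones —
equivalent to rejecting whole 4-block sequences and roughly 50× cheaper.

Matching of the two selected classes controls the forgetting confound.
Suspicious streaks follow alternation-rich stretches, so any observer —
leaky or change-aware — enters them with systematically fresher evidence
about the probed transition, and forgetting alone would then produce a
spurious streak-type effect. The two classes are therefore matched not
only on mean duration (tolerance 0.25 trials) but on the *change-blind
reference observer's own predicted confidence change*: an uncoupled
filter is run over the same sequence and the class means of its
pre-to-post confidence change are matched to 0.05 log-precision units.
With the null observer's predicted change equalized by construction, a
residual streak-type contrast can only reflect inference about shared
change points. Measured over 40-design pools, the model-level contrast
(non-suspicious minus suspicious change in confidence about the probed
transition) is ≈ +0.47 log-precision units for the coupled hierarchical
observer and statistically indistinguishable from 0 for the flat and
uncoupled observers, on both the coupled and the uncoupled task.

Accepted designs record their seed and regenerate bit-exactly.

## Fitting

Each observer has one free parameter (ω or p_c), fitted by grid search —
log-spaced defaults: p_c over 1e−4–0.5 and ω over 1–10³, 61 points —
minimizing SSE between the model's predictive probability and either the
generative probability of each observation (all trials) or the subject's
probability reports (question trials only). Subject confidence lives on
a bounded slider while model confidence is an unbounded log-precision,
so the confidence objective is the residual sum of squares of a
per-subject linear regression (pooled across blocks) of reported on
model confidence. Ties break toward the smaller (more forgetful)
parameter. Model comparison uses paired MSE differences at question
trials, with the same residual treatment for confidence.

Fitting p_c to sequences generated at volatility 1/75 recovers the
truncation-corrected rate 0.0144 stably (16 experiments suffice for the
argmin to settle within one grid step); the SSE valley is extremely
shallow (±0.2% over a ±30% parameter range), so small-sample fits can
wander a step or two.

## Synthetic subjects

A subject is an observer trace plus a report model, emitted in the
9-column trial-matrix layout (modality, block, stimulus, the two cross
transition probabilities, probability report, confidence report, two
reaction times; NaN outside question trials; reaction times always NaN —
not modeled). Probability reports compress the predictive probability
toward 0.5 (slope 0.7) plus Gaussian noise (sd 0.2), clipped to [0, 1];
confidence reports are an affine map of log-precision onto the slider
(slope 0.21, intercept −0.3) plus noise (sd 0.10), clipped.

Calibration targets, in order of priority: the group regression of
probability reports on optimal estimates (slope ≈ 0.66–0.68, Pearson
ρ ≈ 0.55) and the size and precision of the confidence streak-type
interaction (≈ +0.10 slider units with between-subject s.e.m. ≈ 0.02,
comparable to human cohorts on this task). A single i.i.d. slider-noise
parameter cannot simultaneously reproduce humans' low *global*
confidence correlation with the optimal observer (≈ 0.2) and the
precision of their pre/post confidence differences; the calibration
favors the latter, so synthetic confidence reports are globally more
reliable than human ones (ρ ≈ 0.8). The noise model is a calibration of
report reliability, not a claim about the human report-generating
process; passing cohort tests show that the analysis pipeline recovers
each source model's signature at realistic effect sizes, not that humans
have this noise structure.

Cohort studies draw each subject's design from a pre-assembled pool
(24 coupled-task designs, 42 control-task designs in the acceptance
tests; random assignment without replacement), mirroring the per-subject
sequences of the behavioral study. With 23-subject cohorts,
hierarchical-source cohorts show the confidence contrast at t > 2 in
virtually every draw (effect +0.104 ± 0.016, matching the human
0.10 ± 0.03), while flat-source and uncoupled-task cohorts stay below
|t| = 2 in ≥ 95% of draws, and probability reports show no contrast.

## Simulation studies

**Apparent learning rate.** Frequency-mode task, 800 trials; 7 change
points every 100 trials (low volatility) plus 8 interleaved ones (high
volatility); rates redrawn uniformly on 0.1–0.9; flat prior counts
[1 1]. Both models' parameters are fitted once to the generative rates
of both conditions jointly and then held fixed. The apparent learning
rate is (θ_{t+1} − θ_t)/(y_{t+1} − θ_t), masked where |prediction
error| < 1e−6. Both models — including the flat one with a fixed
leak — show transient post-change-point peaks and a higher mean rate
under high volatility (sign tests over 200 repetitions in the tests;
1000 by default), so such modulations are not evidence of hierarchy.
Change-point positions are configurable; the conclusions do not depend
on them.

**Estimate-vs-confidence correlation.** For each (volatility, odds-step)
cell: fit both models to the generative rates of 25 training sequences
(380 trials each), then correlate their pooled trial-wise outputs on 25
fresh sequences. At the experimental regime (0.013, fourfold) the
probability estimates correlate at ρ ≈ 0.98 while confidence correlates
at ρ ≈ 0.55–0.65; the estimate-confidence gap holds across the grid.
Desk-scale defaults (25 sequences/cell, 31-point parameter grids) keep a
cell under ~5 s; the paper-scale 100 sequences/cell only narrows the
Monte-Carlo error (cell ρ varies by < 0.02 between independent
25-sequence batches).

## Numerical choices and degenerate inputs

Uniform midpoint grid; prior moments for the look-ahead mixture computed
on the grid itself so limits hold to machine precision. Posterior mass
underflow raises rather than silently renormalizing zeros. Zero-variance
(single-point) posteriors raise. The flat observer's [0 0]-prior
confidence is NaN until relevant data arrive. Exclusion of synthetic or
real subjects uses the per-subject Pearson ρ between probability reports
and optimal estimates with a strict ρ < 0.18 cut. Learning-rate ratios
are masked, not clipped. All randomness flows through
`numpy.random.Generator` seeds; design assembly stores its seed and all
tests and the acceptance script are seeded.

## Limitations

* Synthetic confidence reports are more reliable than human ones (see
  calibration note); conclusions about detection rates transfer to data
  of comparable reliability only.
* Reaction times are carried as layout columns but never modeled or
  analyzed.
* The uncoupled variant assumes fully independent change processes; the
  intermediate regime (partially correlated change points) is not
  implemented.
* Structure identification (coupled vs uncoupled) is limited to the
  exposed log-evidence accessor; no inference over p_c itself.
* The deposited-data reproduction path is implemented and tested against
  synthetic cohorts written in the same trial-matrix layout; the
  behavioral file itself is not distributable with the package, so that
  test is red unless the file is supplied.
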