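# Methods

## Model and estimation

Each recording session's structured-condition trials are modeled by a
hidden Markov model over Q latent states.  A state is a quasi-stable
multichannel voltage configuration: its emission is a single N-dimensional
Gaussian with full covariance.  The per-state Gaussians realize the
Gaussian-mixture emission family in its one-component-per-state form: the Q
mixture components fitted to the pooled frames become, one-to-one, the Q
HMM states.

Estimation per session:

1. **Frame pooling.** Every frame of every trial in the (session,
   condition) cell is pooled, discarding within-trial timing.  The pool
   size equals the summed trial lengths.
2. **K-means seeding** (scikit-learn, k-means++ with 5 restarts, best
   inertia kept): cluster means become the first guess of the component
   means; each component's covariance is the sample covariance (divisor
   *n*) of the frames nearest its mean; weights are cluster occupancies.
3. **Mixture EM** on the pool, full covariances, until the relative
   log-likelihood change falls below 1e-6 or 200 iterations.
4. **HMM initialization**: emissions and priors from the mixture, uniform
   transition matrix.
5. **Baum-Welch** over all trials jointly.  Forward/backward run in log
   space (log-sum-exp), batched across trials with per-trial length masks,
   so epochs of thousands of frames cannot underflow and sequences of
   unequal length pool their expected sufficient statistics exactly.
   Stops below 1e-6 relative change or at 100 iterations.  All parameters
   (π, A, emissions) are re-estimated; holding π and A at their
   initialization is *not* done — this is the standard multiple-sequence
   Baum-Welch and is recorded here as a modeling assumption.

Numerical safeguards: every covariance update receives a scale-aware ridge
`reg_covar · trace(C)/N` on the diagonal (default `reg_covar = 1e-6`;
falls back to `reg_covar · I` for zero scatter), making all covariances
strictly positive definite without distorting well-conditioned ones.
States whose expected occupancy drops below one frame keep their previous
emission for that iteration instead of being deleted.  The covariance
divisor is *n* (population convention) throughout.

Conventions: the transition matrix is stored row-stochastic,
`A[i, j] = P(next = j | current = i)`; serialized model files write the
column-stochastic transpose (`a_ij = P(current = i | previous = j)`) and
the loader converts back, so both conventions are explicit at the
boundary.  Viterbi breaks ties toward the lower state index, making
decoding deterministic; per-frame posterior-argmax decoding is available
as an option but Viterbi is the default segmentation decoder, because
stable runs (not frame-wise marginals) are the object of the dwell-time
analysis.

## Classification and statistics

The discrimination function of trial x is
`d(x) = log p(x | model₂) − log p(x | model₁)`; positive favors session 2.
Accuracy is the ROC area of d over the test trials, equal to the
Mann-Whitney U statistic divided by n₁n₂ with ties counting ½
(scikit-learn's `roc_auc_score`).  Cross-validation draws stratified 90/10
train/test splits, ten by default; a disjoint stratified 10-fold mode is
available and is preferred when the *distribution* of per-split areas is
itself analyzed, since repeated random draws share test trials and their
areas are positively correlated.  A configurable held-out validation
fraction (default 15%) can be removed before any model selection.

State counts (Q₁, Q₂) are selected over the full Cartesian grid (3–8 each
by default, 36 cells) by maximal mean CV area, ties toward smaller
Q₁ + Q₂.  The grid is joint rather than per-day because the selection
criterion — classification accuracy — is a property of the pair.

Fixed-prior accuracy assigns each trial to
`argmax_k [log p(x | model_k) + log w_k]` with w the training class
proportions; with equal proportions this is exactly the sign of d.
Distribution comparisons use Welch's unequal-variance t-test (the
two-sample form for per-split area lists and per-trial duration lists);
identical constant inputs are reported as p = 1 with a warning rather
than 0/0.  The reaction-time baseline fits one 1-D Gaussian per session
to training RTs (variance floored at 1 ms² for degenerate inputs) and
scores by log-density difference.  The score–RT association is the
trial-by-trial Pearson correlation on test sets.

Localization drops each array's selected contact couple in turn and reruns
the entire pipeline on the reduced montage (with optional Q re-selection;
α = 0.01 for array drops, α = 0.05 for within-array contact replacement).
Parameter swapping exchanges one named set (priors, means, covariances,
transitions) between the two models over all injective state matchings of
the smaller model into the larger (all permutations at equal Q), capped at
5040 configurations with seeded uniform subsampling beyond the cap.
Unequal-Q swaps renormalize exchanged stochastic vectors/rows; at equal Q
the swap of all four sets under any permutation is exactly a model
exchange and negates every discrimination score — an identity the tests
verify analytically.  Swap significance is a one-sample t-test of the
per-configuration accuracies against the unswapped accuracy.

## Synthetic study conditions

The generator emulates the structure the decoder targets, with ground
truth retained.  Default ("study-scale") preset:

| parameter | default | rationale |
| --- | --- | --- |
| montage | 8 arrays × 8 contacts; selection keeps 2/array (N = 16) | typical depth-electrode implantation scale |
| informative arrays | 1 of 8 | a focal session effect |
| states | Q = 3 (day 1), 4 (day 2) | small state counts at the lower end of the selection grid |
| background noise SD | 25 µV | ongoing iEEG background amplitude |
| state mean amplitude | 100 µV (Gaussian across informative contacts) | evoked deflections of order 100 µV on depth contacts |
| covariance scale (day 2) | 2× on informative contacts | the session effect carried by emission covariance |
| self-transition | 0.980 / 0.9824 per frame at 512 Hz | state dwell ≈ 98 / 114 ms, the ~100 ms time scale of momentary voltage configurations |
| trial length | N(600, 70²) ms day 1, N(575, 70²) ms day 2, floor 3 frames | serial reaction-time-task latencies, day 2 slightly faster |
| trials | 60 S + 20 C per day | a realistic single-patient session |
| RT coupling | RT = trial length | epochs end at the key press, so duration *is* the RT |
| sampling | 512 Hz | clinical iEEG rate |

Noise contacts have state-*independent* emissions, so the session effect
(covariance scale and dwell) is confined to the informative array; the
control condition is drawn from a single session-invariant model for both
days, so its only session-dependent property is trial length.  Hidden
paths are sampled exactly via geometric dwells plus the embedded jump
chain.

What the generator does **not** emulate: 1/f spectral structure,
epileptiform artifacts, volume conduction, cross-contact correlation of
the background noise (covariances are diagonal), non-stationarity within
a session, and response errors.  Passing tests therefore demonstrate the
estimator and the inference chain, not robustness to these properties of
real recordings.

## Problem sizes and presets used in tests and the acceptance script

The study-scale preset (512 Hz) is used where parameter recovery against
ground truth is the point.  Property-style checks that need many repeated
model fits run the *same* conditions on a coarser time grid — the
`fast_preset` (128 Hz) and the 64 Hz variants re-derive the per-frame
self-transition probabilities so state dwell times and trial durations in
milliseconds are unchanged; only the number of frames per trial shrinks.
The null-safety check uses 120 trials/day, identical generative models on
both days, 20 seeded repetitions, and the disjoint 10-fold split mode (see
above for why).  These sizes are the package's own choices for routine
verification; all entry points accept the full-scale settings.

## Known limitations

* Baum-Welch converges to a local optimum; the only randomness is the
  K-means seeding (5 restarts by default).  Distinct seeds can select
  different local optima on weakly structured data.
* The Q-grid search refits every cell independently (36 × 2 models × 10
  splits at defaults); no warm starting across cells.
* Unequal-Q parameter swaps involve renormalization choices (documented
  above) that the equal-Q case does not need; only the equal-Q identities
  are exact.
* The epoch container stores matrices in a NumPy `.npz` archive next to a
  TSV manifest — compact and exact, but not language-neutral; export to
  other ecosystems goes through the TSV manifest plus per-trial text
  matrices if needed.
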