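# Methods

This note describes the models and procedures implemented in `hypnofuse`,
the choices made where the design was genuinely open, and what the synthetic
test bed does and does not establish.

## Setting

Sleep is scored visually in 30-s epochs into the five AASM stages W, N1, N2,
N3, R. Inter-rater agreement on the same recording is limited (roughly
70–85 % overall, far lower for N1/N3), so a database scored by J physicians
carries information beyond any single hypnogram: where the scorers disagree
and by how much. `hypnofuse` implements the fusion of such multi-scored
annotations, their use as smoothed training targets for probabilistic
stagers, and metrics that score a stager against the *group* rather than a
single reference.

Stage indices are fixed package-wide as W=0, N1=1, N2=2, N3=3, R=4. Two
sentinels appear in real data: `NC` (epoch seen but not classified) and `-`
(no annotation). They are distinct tokens on disk but deliberately
indistinguishable to every computation: both simply reduce the number of
valid observations M at that epoch. Epochs with *no* valid annotation carry
no label information and are dropped (`filter_nc_epochs`); partially
annotated epochs are kept with their reduced M.

## Consensus machinery

**Leave-one-out probabilistic consensus** `z^j`. For scorer j and epoch t,
count the valid votes of the other J−1 scorers per stage and divide by the
maximum count. The majority stage — and every stage tied with it — scores
exactly 1; minority stages score count/max. Epochs where no other scorer
voted are masked invalid.

**Soft-Agreement** of scorer j is the mean of `z^j` evaluated at j's own
labels, over the epochs where j has a valid label and `z^j` is defined; the
divisor is the number of contributing epochs (with complete annotations this
is T). It is 1 for a scorer always in the majority or a tie, 0 for one who
never matches any majority/tied stage. Ranking is per recording; equal
scores are broken by input scorer order (a stable sort), making the ranking
deterministic.

**Soft-consensus** is the per-epoch empirical vote distribution: occurrences
of stage k over the M valid observations. Rows sum to 1 and every entry is a
multiple of 1/M. It doubles as the hypnodensity ground truth.

**Majority vote**. The consensus label is the argmax of the soft-consensus
row. Ties are resolved by the most reliable scorer; since a consensus label
must attain the row maximum, we take the highest-ranked scorer *whose label
is among the tied stages*, descending the ranking until one is found (one
always exists — each tied stage received at least one vote). This keeps the
"most reliable scorer decides" rule while guaranteeing the argmax invariant
even when the top scorer's vote lost the ballot or is missing.

## Label smoothing

Targets for training are convex combinations
`y = (1−α)·onehot + α·q` with q either the uniform distribution 1/K
(`LS_U`, α ∈ (0, 0.5], grid step 0.1) or the epoch's soft-consensus row
(`LS_SC`, α ∈ (0, 1], grid step 0.1; α = 1 trains on the scorers'
distribution alone). The soft-target cross-entropy uses the natural
logarithm, mean reduction over the epochs in a batch, and clamps predictions
at 1e-12 before the log. Because the combination is affine in α, the LS_SC
loss decomposes exactly into (1−α)·(base loss) + α·(cross-entropy to the
soft-consensus), which the tests verify numerically.

## Metrics

* **Performance** (per subject): accuracy, macro-averaged F1, weighted F1
  (class weight = number of true instances, the convention for the heavily
  imbalanced stage distribution), per-class F1 and Cohen's kappa. Computed
  with scikit-learn; a class absent from both vectors scores F1 = 0 with a
  warning. Aggregation across subjects is the unweighted mean (± sd for
  ACS).
* **ECE**: confidences (per-epoch max probability) fall into M equal bins
  ((m−1)/M, m/M]; ECE is the bin-count-weighted mean |accuracy − mean
  confidence|. M defaults to 10 (the convention of the calibration
  literature); a confidence of exactly 0 — unreachable after argmax with
  K = 5 — would go to bin 1. The overall mean confidence is reported
  alongside.
* **ACS**: the mean over epochs of the cosine similarity between the
  predicted row and the soft-consensus row; 1 iff the model reproduces the
  scorers' distribution up to scale, 0 for disjoint support. Differences in
  ACS between arms are tested with a paired two-sided Wilcoxon signed-rank
  across subjects — our choice of test, made explicit because it matters
  for small cohorts.

## Synthetic test bed

The generator emulates a multi-scored database without signals:

* **Truth**: a first-order Markov chain over the five stages. The default
  kernel is the sticky construction P = (1−b)·I + b·1πᵀ with b = 0.08 and π
  the healthy-cohort stage marginals (W .125, N1 .059, N2 .487, N3 .140,
  R .190). Its stationary law is exactly π and bouts are geometric with
  mean 1/b = 12.5 epochs (≈ 6 min), a realistic bout scale. It does not
  model sleep-cycle periodicity, stage-transition asymmetries (e.g.
  N2→N3→N2 laddering) or time-of-night effects.
* **Scorers**: scorer j reproduces the true stage with probability r_j,
  otherwise draws from a confusion kernel concentrated on the clinically
  confusable pairs (W–N1, N1–N2, N2–N3, N2–R). The kernel's diagonal is
  zero, so each scorer's marginal accuracy is exactly r_j. Defaults: five
  scorers with r = 0.60, 0.675, 0.75, 0.825, 0.90, matching the spread of
  reliabilities seen in real multi-scored cohorts. An `isrc_config` preset
  gives six scorers, a wider spread (0.50–0.92) and i.i.d. missing/NC
  injection (5 %/2 %). Scorer errors are conditionally independent given
  the truth — real scorers share systematic biases, which this does not
  model; consequently consensus quality is somewhat optimistic.
* **Features**: per-epoch isotropic Gaussians centred on a per-stage mean
  (default: 5 dimensions, separation 2.0, sd 1.0), chosen so a reasonable
  classifier lands in the high-70s % accuracy range against the consensus —
  the realistic regime for staging. There is no temporal context in the
  features.
* Cohort size defaults to 40 subjects × 960 epochs (8 h nights). All
  randomness flows from one seed via `numpy` SeedSequence spawning;
  datasets are bit-reproducible from (config, seed).

## Reference classifier and experiment protocol

The package's contribution under test is the *target construction*, which is
architecture-agnostic; the reference model is deliberately minimal: a
feed-forward softmax network (one hidden layer of 32 ReLU units by default)
written in NumPy, trained with Adam (lr 1e-3, β₁ = 0.9, β₂ = 0.999, batch
128) on the soft-target cross-entropy, with inverted dropout (rate 0.2) on
hidden layers. Early stopping monitors validation weighted F1 once per data
pass; after 5 evaluations without improvement training stops and the
best-validation-F1 parameters are restored. The cap of 30 passes and
patience 5 are sized to this model and data; both are configurable.
Monte-Carlo dropout prediction averages S stochastic forward passes
(dropout active); S = 0 gives the deterministic pass.

`run_experiment` mirrors the standard multi-scored evaluation design:
subject-level k-fold cross-validation (default k = 4; every subject is
tested exactly once) with a rotating held-out validation share (20 % of the
non-test subjects) used for early stopping and for the α grid search. The
smoothing weight is selected per arm by mean validation weighted F1 across
folds — the same metric as early stopping; ACS-based selection is available
as an option since the selection criterion is genuinely underdetermined.
Test predictions are pooled per subject and scored against the majority-vote
consensus (performance, ECE, confidence) and the soft-consensus (ACS).

## What the synthetic results do and do not show

On the default cohort the LS_SC arm consistently raises ACS over the base
arm (mean ≈ 0.827 vs ≈ 0.824 across seeds, per-subject Wilcoxon p ≪ .01 in
each run): smoothing with the scorers' distribution measurably pulls the
model's hypnodensity toward the group consensus even at this small scale.
This is the mechanism the package exists to exercise, demonstrated
end-to-end.

Calibration behaves differently than for large over-confident networks on
real PSG: the small correctly-specified reference model is already
near-calibrated in the base arm (mean confidence ≈ 0.78 vs accuracy ≈ 0.79),
so smoothing makes it mildly *under*-confident and ECE does not improve in
this test bed. ECE gains from label smoothing should be expected only where
the base model over-fits its hard targets; the experiment reports ECE per
arm so this is visible rather than assumed. More generally, passing tests
here certify the correctness of the fusion, smoothing and metric machinery
and the direction of the ACS effect under conditionally independent scorer
noise — not performance on real recordings, real scorer bias structure, or
deep sequence models.

## Numerical details

* Soft-consensus rows are validated to sum to 1 within 1e-12; prediction
  matrices within 1e-9; hypnodensity inputs off by ≤ 1e-6 are renormalised,
  worse rows rejected with the epoch index.
* Degenerate inputs: a recording whose epochs are all NC filters to an
  empty recording with a warning; Soft-Agreement with no contributing
  epochs, cosine with a zero-norm row, and an all-invalid epoch in
  soft-consensus are errors naming the offending scorer/epoch.
* Cohen's kappa of two identical constant vectors is defined as 1 (0 when
  different), replacing the 0/0 form.
* The smallest representable smoothing is α = 0 (returns the one-hot input
  bit-exactly); training with such targets is byte-identical to the base
  arm under the same seed, which the tests assert.
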