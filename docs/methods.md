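# Methods

## The data-generating process the package assumes

A promoter library varies only the spacer between the −35 and −10 elements
of a fixed chassis (sigma70: 17 nt; the sigmaB/F/W chassis use 12/15/16 nt
spacers and are configured by the user, since only their lengths are fixed
by the assay design). Cells carrying the library are sorted by reporter
fluorescence into 12 gates; buffer regions between adjacent gates are
discarded to limit cross-bin contamination from the roughly Gaussian
single-promoter expression profile. Each gate is sequenced with 51-bp
single-end reads in which the spacer occupies a fixed window; any mismatch
in the constant flanks rejects the read (reasons tallied: `flank_mismatch`,
`bad_length`, `ambiguous_base`). Accepted reads + rejected reads always
equal input reads, and reads are taken on the given strand only — the
amplicons are directional. Quality scores are ignored; reads containing N
are rejected. Every distinct spacer string is treated as a distinct
sequence, including spacers that differ only by a sequencing error; the
filtering step is what protects the labels from the resulting artefacts.

## Read-distribution screening and labeling

Per unique spacer, three properties of the bin-count vector **r** are
computed over multi-read sequences:

* `r_tot = Σ rᵢ`;
* the number of similar-height maxima: the primary bin M1 is the global
  maximum of **r** (lowest bin on ties — M1 is the label bin, so this
  matches the label tie-break); a strict local maximum M2
  (r[M2−1] < r[M2] > r[M2+1], missing neighbours = 0) qualifies when
  r[M2]/r[M1] > 0.66 and r[M1] > r[M2] > 0;
* the largest |M1 − M2| over qualifying pairs (0 if none).

Taking M1 as the global argmax rather than restricting it to strict local
maxima matters only for plateau-shaped vectors (equal adjacent counts),
which are otherwise left without a primary peak; plateaus themselves are
never counted as local maxima.

A sequence is removed when any property strictly exceeds that property's
95th percentile (linear-interpolation percentile over multi-read
sequences). Strict inequality means exact ties with the threshold survive,
which keeps "the top 5%" semantics as closely as an integer-valued
statistic allows. Single-read sequences bypass the screen — they carry no
distributional evidence either way. Thresholds are computed once and
applied once.

Labels: the bin with the most reads, ties to the lowest bin (deterministic,
and never overstates TIF). For TIF models bin 0 — background fluorescence,
dominated by reporter-inactivating mutations and cell defects rather than
promoter sequence — is zeroed before the argmax, and bin-0-only sequences
are rejected; bins 1–11 map to classes 0–10. Orthogonality data keep both
of their two bins (fluorescent under a noncognate sigma = loss of
orthogonality = positive class).

## Model and training

Architecture (per chassis, input length L configured, no cross-chassis
padding): three stride-1 valid convolutions with 4 (1×1), 16 (1×4) and
32 (1×2) kernels, ReLU after every conv and dense layer, one dropout layer
(p = 0.3) after the conv stack, dense layers of 128 and 64 units. The
ordinal head computes s = w·x and ôᵢ = sigmoid(s + bᵢ) for ten biases
initialised strictly decreasing (linspace 1 → −1) so thresholds start
ordered.

Losses: ζ_out is the weighted multilabel binary cross-entropy — mean over
the batch of wₙ(y) Σᵢ BCE(ôᵢ, oᵢ) with prefix targets oᵢ = 1[i < y] and
probabilities clamped to [1e−7, 1 − 1e−7]; ζ_aux = Σ softplus(bᵢ₊₁ − bᵢ)
over the nine adjacent bias pairs, a soft ordering penalty that is minimal
but positive when the order is correct (a hard constraint would oscillate).
The trained total is exactly ζ = ζ_out + ζ_aux. Class weights are inverse
frequency, wₙ = N/(K·n_c), so balanced data reduces to unweighted training
and doubling all counts changes nothing.

Optimisation: Adam (lr 1e−3, β = 0.9/0.999), batch 256, up to 100 epochs,
early stopping at the minimum validation ζ with patience 10. Splits are
70/10/20 train/validation/test, stratified by class (the validation set is
1/8 of the non-test 80%); 5-fold evaluation uses stratified folds with the
fold's 20% as test. All randomness — initialisation, shuffling, dropout,
splits — flows from one seed, so identical seeds give identical loss
histories. If a class is too small to stratify, the split falls back to a
plain random split with a warning rather than failing.

Prediction: class probabilities by differencing the thresholds
(Pr(y=0) = 1−ô₀, Pr(y=i) = ôᵢ₋₁−ôᵢ, Pr(y=10) = ô₉ — the unique assignment
consistent with Pr(y > 10) = 0 and normalisation); if thresholds are
non-monotone (possible early in training) negative entries are clamped to
zero and the vector renormalised, with a warning flag on the result. The
predicted class is the argmax, ties to the lower class; under a monotone
head this coincides with counting thresholds above ½. A practical note:
under-trained models (few epochs, small data) have diffuse threshold
ladders, and the argmax then concentrates on the extreme classes even while
the latent score already ranks sequences well — rank metrics converge
before calibrated per-class argmax accuracy does.

The binary orthogonality model shares the trunk, replaces the head with a
single sigmoid output and plain BCE, and reports test ROC AUC.

## Synthetic sort-seq generator

The generator exists so the pipeline can be exercised end-to-end against
known truth. Defaults (chosen once as the package's working conditions):

* planted truth: random additive per-position base effects, standardised so
  a uniform random spacer has latent mean 0, variance 1; optional pairwise
  interaction terms and a GC coefficient support epistatic truths;
* gates: 10 interior bins of width 0.5 on [−2.5, 2.5] with open-ended
  outermost gates, so tail TIFs are represented the way a sorter's extreme
  gates capture sub-0.01% population fractions;
* buffers: 0.025 latent units (5% of a bin width) carved symmetrically at
  each internal edge; buffer-falling cells are discarded;
* noise: one Gaussian intrinsic term per cell (sd 0.35 ≈ 0.7 bin widths);
  extrinsic noise is deliberately not modelled — the real assay normalises
  it away with a constitutive reference, and the binning step itself cannot
  see it;
* 50 cells per sequence; by default every sorted cell is kept as a read;
  when a per-bin depth is requested, each bin's pool is subsampled without
  replacement (multivariate hypergeometric across sequences), with a
  warning when the request exceeds the pool;
* 20,000 sequences for the recovery fixture.

Under these defaults the labeled classes span all 11 bins. What passing
tests on this generator shows: the filtering, labeling, training, metric
and design machinery is correct, and the model family can recover a planted
monotone sequence→TIF map (held-out Spearman vs planted latent well above
the ≥ 0.7 bar we assert; the acceptance script reports the measured value).
What it does not show: performance on real libraries, where the truth is
non-additive, the noise has extrinsic components and gate occupancies are
highly skewed — rank correlations against real sorted labels are expected
to be substantially lower than against planted truth.

## Forward design

Candidates are distinct uniform-random spacers (seeded; generation refuses
n > 4^L). Ranking is a stable descending sort by (predicted class,
probability of that class), with lexicographic spacer order as the final
tie-break, so the ranking is permutation-invariant. Novelty uses the
minimum Hamming distance to the training set with an admission band of
[2, 5]: distance ≥ 2 excludes training sequences and their trivial
single-mutation neighbours, ≤ 5 keeps candidates inside the sequence
neighbourhood the model has evidence for. The default panel is up to 4 per
class plus 10 "high" candidates — the class-10 predictions with the largest
Pr(y = 10) — capping at 54; classes with too few qualifying candidates are
reported as shortfalls and never padded. "Highest probability" is
interpreted as Pr(y = 10) rather than the latent score; the two orderings
coincide for a monotone head.

## Validation arithmetic

Corrected fluorescence = (mKate2 − blank)/(sfGFP − blank); a non-positive
reference denominator is an error, not a value. The per-promoter value is
the mean of replicate corrected fluorescences (8 replicates in the intended
design), then x = (log P − log P_min)/(log P_max − log P_min) across
promoter means — normalisation after averaging, using per-promoter-mean
extremes. The panel regression is OLS of x on predicted class; R² comes
from the fitted model (and matches an independent two-pass 1 − SSres/SStot
to 1e−10 in tests); Spearman rho is the same average-rank-ties
implementation used by the evaluation metrics. The 95% CI per class mean is
a t interval on within-class replicate promoters; the 50% prediction
interval uses the regression residual variance with n − 2 df, the standard
se √(σ²(1 + 1/n + (x−x̄)²/Sxx)) form.

## Numerical and degenerate-input choices

* BCE probability clamp 1e−7; sigmoid computed in the numerically stable
  split form; softplus via logaddexp.
* Percentiles: NumPy linear interpolation.
* Macro metrics skip classes absent from the truth vector (with a warning);
  prediction-distribution rows for absent classes are NaN, never
  fabricated.
* Spearman on a constant vector is an error, not a silent 0.
* Empty bin tables, empty candidate lists, degenerate normalisation ranges
  and out-of-range labels raise immediately with named reasons.

## Known limitations

* Spacer-internal sequencing errors are not modelled or corrected; they
  appear as spurious rare sequences and are mostly caught by the multi-read
  property screen or diluted by read-count weighting of the label.
* The simulator's gate boundaries are regular by construction; it makes no
  claim of matching empirical bin occupancies beyond spanning the class
  range.
* One model per chassis; no parameter sharing or padding across spacer
  lengths.
* Saliency/attribution for trained models is out of scope; only per-class
  position frequency matrices and GC-content summaries are provided for
  sequence interpretation.
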