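# Methods

`prpkit` re-implements, as a tested pipeline with synthetic ground truth, a
family of EEG analyses used to study the cortical distinctiveness of speech
sounds in continuous listening: phoneme-related potentials (PRPs), compact
convolutional phoneme decoding with uncertainty, attribution-based relevance
statistics, representational similarity analysis (RSA) against binary
phonological features, boosting temporal response functions (TRFs) for
acoustic tracking, and the associated inferential layer.  Because raw
recordings from such studies are rarely redistributable, every stage is
validated against a generator that plants known effects and known kernels.

## Synthetic cohorts

One simulated participant is a continuous multichannel recording (µV) with a
forced-aligner-style annotation table (onset, duration, phoneme label),
16-column band envelope/onset predictor series, and scalar covariates.  The
recording is a superposition of three parts.

**Phoneme template stream.** Every phoneme instance adds a per-phoneme
template of shape `electrodes x 0.5 s`.  Templates follow

```
template_p = common + alpha * (feature_p + beta * unique_p)
```

* `common` — a small phoneme-independent N1/P2-like evoked response
  (amplitude scale `common_scale = 0.25`).  It is deliberately weak relative
  to the phoneme-specific content: attribution scores scale with input
  magnitude, and a large non-discriminative component would otherwise
  dominate the relevance maps.
* `feature_p` — the sum over the three binary manner features
  ([syllabic], [sonorant], [continuant]) of the phoneme's 0/1 feature value
  times a damped-oscillation time course (4/6/8 Hz) with its own scalp map.
  The three latencies (50/80/110 ms onset) are close together and the
  damping is heavy (one dominant lobe), so the pooled phoneme-specific
  energy has a single peak — a clean latency read-out for the relevance
  analysis.  The maps are broad, mutually orthogonal topographies (a
  monopolar bump plus two dipolar gradients): orthogonality keeps template
  distances faithful to the feature geometry even though the time courses
  overlap.
* `unique_p` — a smooth random pattern per phoneme (shared across the
  cohort, scale `beta = 0.6` relative to the feature part), windowed by the
  same 100–250 ms temporal envelope.  It makes phonemes within a feature
  class separable.

`alpha` is the *distinctiveness* parameter and scales everything that
differs between phonemes: at `alpha = 0` all phonemes evoke the identical
`common` response; lowering `alpha` jointly lowers decodability and feature
alignment, which is exactly the dedifferentiation phenotype the analyses
target.  Participant-level `alpha_i = alpha_group * (1 + 0.15 z_i)`.

**Spatial spread** `sigma` keeps the `ceil(sigma * E)` electrodes with the
largest aggregate template energy (one subset per participant, so the
localization is consistent across phonemes) and attenuates the rest by 90%,
then rescales each template back to its original Frobenius norm.  `sigma`
therefore moves the spatial *distribution* of signal, not its energy —
localized (high relevance dispersion) versus distributed (low dispersion).

**Latency shift** `tau` delays the whole template by `tau` ms (zero-padded).

**Acoustic-tracking stream.** Eight nonnegative band envelopes are generated
as smoothed rectified noise with a shared co-modulation component; onset
series are their half-wave-rectified first differences.  Bands 2–5 of each
family drive the recording through gamma-shaped kernels (onsets stronger and
earlier than envelopes, as in empirical TRFs) on a central scalp bump.
These kernels are the TRF ground truth.

**Noise** is a configurable mixture of white and 1/f-shaped Gaussian noise
(default `noise_sd = 2.5 µV`, equal mixture), added to all channels
including the two mastoid reference channels.

**Annotations** tile each segment with inter-onset intervals drawn uniformly
from 50–250 ms, so responses overlap heavily as in real connected speech.
Phoneme labels are drawn from a Zipf-weighted inventory (ARPABET-style
labels cycling through the four manner classes).

**Covariates** couple to the pooled-standardized realized `alpha` through a
Gaussian copula: `c = r * z_alpha + sqrt(1 - r^2) * eps`, giving exact
target Pearson correlations in expectation.  The default battery mimics an
auditory-aging covariate set: one driver (`abr_wave_i`, r = 0.7 — its
empirical analogue predicts decoding accuracy) and five nuisance measures.

All randomness flows from one root seed split into per-participant streams;
identical configurations reproduce identical cohorts bit for bit.

### Study conditions (desk scale)

The default cohort is 10 participants per group at 64 Hz with 16 scalp
electrodes (+2 mastoids), 12 phonemes (Zipf exponent 0.7), 8 segments of
12 s:

| group | alpha | sigma | tau | emulates |
|---|---|---|---|---|
| A | 1.2 | 0.25 | 0 ms | younger-like: distinct, localized, early |
| B | 0.4 | 1.0 | 80 ms | middle-aged-like: fuzzier, distributed, delayed |

A `paper-scale` preset (61 electrodes, 31 phonemes, 128 Hz, 15 x 60 s
segments, 20 repetitions, 10,000 permutations) reproduces the full-size
protocol; the desk preset exists so that a complete multi-seed validation
runs in minutes on one CPU.

### What the generator does *not* emulate

No audio, no articulatory coarticulation (templates are identical across
instances of a phoneme), no ocular/muscle artifacts, no bad channels, no
volume-conduction forward model, and no participant-level template
geometry differences beyond `alpha`.  Passing recovery tests therefore show
that the *analysis chain* is correct and sensitive under its assumptions —
not that those assumptions hold in real EEG.

## Preprocessing and PRPs

A minimum-phase causal windowed-sinc FIR band-pass (1–15 Hz) is applied to
every channel, followed by re-referencing to the mastoid average (mastoids
are then dropped).  PRPs average epochs in the half-open window
`[onset, onset + 0.5 s)` — exactly 64 samples at 128 Hz.  Labels are
retained when their instance count strictly exceeds 1% of all instances;
labels above the 319-instance cap contribute a seeded random subset
(without replacement, re-drawn per repetition).  Incomplete edge epochs are
dropped with a logged count rather than zero-padded.

## Phoneme decoder

The classifier is the EEGNet-8,2 compact CNN (8 temporal filters of length
fs/2, 2 spatial filters per temporal filter with a max-norm constraint,
separable convolution, two average-pooling stages, ELU, dropout 0.5,
soft-max readout), implemented directly in NumPy with manual
backpropagation.  Training follows the published protocol: cross-entropy,
Adam at 1e-3 decayed by 0.7 every 100 epochs, batch 16, up to 300 epochs,
20 stratified folds holding out 5% with a random 15% of the non-test data
for validation; the lowest-validation-loss checkpoint predicts the test
fold.  Samples are (participant x phoneme) PRPs pooled within group, each
standardized by its own mean and SD; arg-max ties resolve to the lowest
label index.  The desk-scale spec (`desk_spec()`) uses 5 folds, learning
rate 2e-3, at most 80 epochs with patience 15, and single precision —
choices that keep one cross-validated fit in the seconds range without
touching the architecture.

Prediction uncertainty is the Shannon entropy `-sum p ln p` of the
probability vector.  The repeat protocol subsamples the larger group to the
smaller group's size each repetition, re-draws the PRP instance subsets,
and averages accuracy/entropy per participant over the repetitions in which
they took part; confusion matrices are summed within repetition and averaged
across repetitions.

## Relevance attribution

Contribution scores backpropagate reference-based multipliers (rescale
rule) from the target phoneme's pre-soft-max output to the input, against
an all-zero reference — the natural rest point of a band-passed,
baseline-free signal.  Linear layers (convolutions, pooling, inference-mode
batch norm, dense) pass multipliers exactly; the ELU applies the secant
slope `(f(x) - f(x_ref)) / (x - x_ref)`.  The scores therefore satisfy the
completeness identity exactly (checked at 1e-3 relative tolerance at every
call; a violation raises, as it can only indicate an implementation bug).
A gradient-times-input rule is available as a cross-check and agrees with
the rescale rule on purely linear networks.

Each sample is attributed with the model of the test fold it belonged to
(no train/test leakage).  Absolute scores are z-transformed within each
matrix (degenerate zero-variance matrices are excluded with a warning),
then averaged across phonemes and repetitions into one map per participant.
Dispersion is the variance (ddof = 1) across electrodes of time-averaged
relevance; peak latency is the arg-max (earliest index on ties) of the
electrode-averaged time course.

## RSA

Feature RDMs are Euclidean distances between 0/1 feature vectors; neural
RDMs are electrode-pattern distances per time step; alignment is Spearman's
rho on strict upper triangles (constant RDMs yield rho = 0 with a
degeneracy flag).  Forward electrode selection starts from the two most
relevant electrodes (group-mean relevance ranking) and adds the next-ranked
electrode while the time- and participant-averaged rho strictly increases
(ties stop).  Confusion RDMs row-normalize the (repetition-averaged)
confusion counts, symmetrize `(P + P')/2`, and complement; the group
difference in confusion-RDM alignment is tested by independently shuffling
the rows of both matrices 5,000 times, with p the proportion of null
differences smaller than the observed one (one-sided, as printed in the
source analyses).  Phoneme dendrograms use average-linkage clustering of
PRPs flattened over electrodes x 0–350 ms, exported as Newick text.

## Acoustic tracking

Synthetic band envelopes pass through unchanged (onsets derived as
half-wave-rectified first differences); when a waveform is supplied, a
4th-order band-pass filterbank at eight log-spaced bands in 0.02–5 kHz
approximates cochlear analysis, with Hilbert envelopes compressed by
exponent 0.6 and resampled to the EEG rate.

TRFs are estimated per electrode by sparse ℓ1 coordinate boosting over lags
−100..500 ms: design columns are unit-variance lagged predictors; at each
step the fixed-magnitude increment (0.005 of the response SD) that most
reduces the training ℓ1 error is applied; the exact improvement is
evaluated on the 32 coordinates with the largest ℓ1 subgradient (refreshed
every 5 steps), which tracks a full exact search at a fraction of the cost.
Early stopping keeps the kernel with the lowest validation ℓ1 error (one
training segment, rotating with the fold index).  The outer loop is
segment-wise cross-validation (default 5 folds of contiguous segments);
held-out segments are predicted with the fold's kernel and r is the Pearson
correlation per electrode averaged over folds.  Unique variance Δr of a
predictor family is r(full) − r(model without that family).  The ROI is the
electrode set in clusters with Δr significantly above zero (one-tailed
one-sample cluster-mass permutation over all participants); each
participant's tracking score is their mean Δr over the ROI.

## Statistics

* **Separability curve** — at each time step and electrode, the one-way
  between/within mean-square ratio with phonemes as groups and participants
  as replicates, averaged over electrodes; zero within-variance points are
  flagged undefined, never silently zeroed.
* **Cluster-mass permutation test** — mass-univariate t maps thresholded at
  uncorrected p ≤ 0.05 (one-tailed one-sample with sign flips; two-tailed
  independent with label exchanges), connected same-sign clusters under a
  declared adjacency (electrodes within 1.5 x median nearest-neighbor
  distance on the layout, or a chain over time), cluster mass = summed t,
  corrected p against the maximum-mass null, t_max reported per cluster.
  The plain-proportion p is the default (`smoothing=False`); the
  `(1+k)/(1+n)` variant is available.  Calibration: family-wise type-I
  error sits inside the 95% binomial band around 0.05 over 200 null runs.
* **Group tests** — Welch's t (Satterthwaite df, Cohen's d, 95% CI) and
  Mann-Whitney U with tie-corrected normal z, no continuity correction.
* **Transforms** — rationalized arcsine units
  `(146/pi)[asin sqrt(x/(n+1)) + asin sqrt((x+1)/(n+1))] - 23` (maps n/2 of
  n to exactly 50); words-in-noise SNR loss `26 - 0.4 n` dB; EHF threshold
  transform `ln(threshold + 25)` (natural log).
* **Backward stepwise regression** — predictors z-scored; OLS;
  `AIC = n ln(RSS/n) + 2(k+1)` (Gaussian form without the 2π constant —
  only differences matter); the single predictor whose removal lowers AIC
  most is dropped until no removal lowers it; the final model is refit and
  reported with standardized betas.  The residual group test fits the
  selected model on all participants pooled and Welch-tests the residuals
  between groups.

## Validation experiments (`prpkit.recovery`)

`cohort_recovery` runs the full decode → attribute → align chain on the
default cohort for one root seed and tests every planted contrast
(Mann-Whitney for accuracy/entropy/latency, Welch for dispersion,
cluster permutation over time for the alignment curves, requiring a
positive cluster touching the first 250 ms).  `trf_recovery` checks kernel
recovery on a noiseless convolution fixture; `trf_null` the prediction of
independent noise; `cluster_calibration` the type-I error;
`stepwise_recovery` whether the alpha-coupled covariate survives selection
(outcome = standardized alpha + noise at n = 40) and whether a pure-noise
outcome against four nuisance covariates most often yields the
intercept-only model.  `scripts/acceptance.py` executes all of these from
scratch and writes a JSON summary.

## Numerical choices and limitations

* Convolutions in the CNN run as circular FFT products with
  `nfft >= T + L - 1` (exact, no wraparound); gradients were verified
  against finite differences.
* The desk protocol trains in single precision; accuracy/entropy metrics
  agree with double precision to the printed precision.
* The boosting candidate short-list (top-32 subgradient coordinates) is an
  approximation to the full exact ℓ1 search; on the test fixtures it
  reaches kernel correlations > 0.95, and the scaling identity
  (doubling predictor amplitude halves kernels) holds exactly.
* Group-size balancing drops participants at random each repetition, so
  per-participant averages can rest on different repetition counts
  (reported as `n_reps`).
* The relevance statistics inherit attribution's input-magnitude
  sensitivity: a large phoneme-independent response component would bias
  peak-latency estimates, which is why the generator keeps `common` small.
  Real data contain such components; interpreting empirical relevance
  latencies requires the same caution.
* The forward-selection stopping rule is strict improvement with no
  tolerance; with noisy alignment estimates the selected set can admit an
  electrode on a chance improvement.
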