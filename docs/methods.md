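# Methods

This note documents the models, estimators, numerical choices and known
limitations of `eegmdd`. Everything quantitative stated here is computed by
the test suite or by `scripts/acceptance.py`; nothing is quoted from external
data.

## Synthetic cohort model

Real clinical recordings are not distributable, so the generator
(`eegmdd.synth`) produces cohorts with exactly the statistical structure the
analysis targets. Each subject's 29-channel signal is a sum of:

1. **Five narrowband oscillators**, one per canonical band: white Gaussian
   noise filtered by a 4th-order Butterworth band-pass (zero phase), then
   normalized to unit variance and scaled to a per-band amplitude. Filtered
   noise rather than sinusoids gives realistic, non-degenerate spectra for
   Welch-type estimation. Generation pads the noise by four low-frequency
   cycles at each end and trims after filtering; without this the filter's
   settling transients dominate the normalized signal at the recording edges
   and masquerade as artifacts.
2. **A 1/f^α background** (α = 1 by default), realized by FFT spectral
   shaping with the power law applied above 0.5 Hz and a plateau below.
   Sub-0.1-Hz power is outside the analysis band and would only produce
   high-pass edge transients downstream.
3. **Shared lagged sources** realizing inter-regional phase coupling: for a
   region pair with coupling c ∈ [0, 1], both regions' channels receive a
   common narrowband source with weight √c — lagged by a quarter cycle of
   the band's center frequency in the second region, which maximizes the
   imaginary cross-spectrum that wPLI measures — plus independent noise with
   weight √(1−c), keeping unit band variance.
4. **Optional artifact transients**: raised-cosine bumps (0.2 s, default
   peak 150 µV on 1–3 random channels) at Poisson-distributed times,
   default 0.5/min. They exist so amplitude-based epoch rejection has
   something real to do.

Baseline band amplitudes (µV, standard deviation): δ 5, θ 3.5, α 6, β 2.5,
γ 1.5; background 3. Alpha dominance matches eyes-closed resting EEG, and
the total (~10 µV rms) keeps an artifact-free signal comfortably below the
80 µV rejection threshold. A per-subject log-normal amplitude jitter
(sd 0.1 on the log scale, shared across a band's channels) supplies
between-subject variability so group statistics are non-degenerate and
calibrated.

**Planted group effects** (the defaults; every value configurable): patients
get ×1.5 delta in both occipital ROIs, ×1.4 theta in the right occipital
ROI, ×0.67 alpha across the four posterior ROIs; phase coupling on five
long-range pairs is 0.6 (HC) vs 0.25 (MDD) in alpha and 0.1 (HC) vs 0.45
(MDD) in gamma. These magnitudes were chosen once to make the pattern
detectable at 15 subjects per group with 60-s recordings — the scale at
which the recovery checks run — and are not tuned beyond that.

What the generator does **not** emulate: volume conduction from real
sources (a forward head model), realistic blink/EMG morphology, non-
stationarity across the recording, severity gradients (HAMD-17 correlates
with nothing by construction), or site/hardware effects. Passing tests
therefore demonstrate that the pipeline recovers the effects it assumes, not
that those effects exist in any clinical population.

A note on the common average reference: because CAR mixes every channel into
every other, planted coupling differences spread weakly into non-planted
region pairs. This is faithful to how reference choice behaves on real scalp
data and is why group differences in wPLI appear "across all regions" rather
than only on the planted pairs; the recovery criterion therefore checks the
planted pairs' signs and significance, not exclusivity.

## Preprocessing

Order: band-pass 0.1–80 Hz and notch 49–51 Hz (both 4th-order Butterworth,
forward–backward so the phase response is exactly zero — phase distortion
would bias wPLI), polyphase downsampling to 500 Hz, spherical-spline
interpolation of bad channels (MNE's Perrin implementation, stiffness m = 4,
standard 10-05 template positions since no digitization exists), 2-s
non-overlapping epochs, rejection of epochs with any |sample| > 80 µV, then
common average reference. Rejection runs on the recording (Pz) reference so
a single-channel artifact is judged before CAR spreads it; CAR afterwards is
identical to CAR on continuous data because it is a per-sample linear map.
The forward–backward filter needs reflection padding of ~3/f_hp seconds
(15000 samples at 500 Hz for the 0.1 Hz corner); scipy's default padding is
orders of magnitude too short and leaves edge ringing. ICA-based ocular
cleaning is deliberately out of scope: it is not identifiable on synthetic
data without modeled blinks; amplitude rejection covers the artifact classes
the generator produces.

## Spectral features

Per 2-s epoch: Hann-windowed periodogram over the whole epoch (one Welch
segment, `detrend=False`), 0.5 Hz grid at 500 Hz — fine enough to resolve
the 1 Hz delta edge. Band integration uses half-open intervals [lo, hi) so
the shared edges 4, 8, 13, 30 Hz count exactly once. Relative power is
computed **per channel** and then averaged within each ROI; the reverse
order (average absolute power, then normalize) would break the sum-to-1
invariant per ROI and weight high-amplitude channels more. Epoch-level rows
feed the classifier (one sample = one epoch); the per-subject mean over
retained epochs feeds the group statistics. Midline channels Fz, Pz, Oz
belong to no ROI and enter only the connectivity analysis; the left-temporal
ROI uses F7 (recorded) in place of the unrecorded FT7.

## wPLI

wPLI = |E[Im S]| / E[|Im S|] over complex cross-spectral observations, with
the 0/0 case (identical or exactly zero-lag signals) defined as 0. The
cross-spectrum is summed over a band's frequency bins *before* the ratio —
per-bin ratios would create many degenerate zero-denominator cells. The
observation unit differs by level: subject-level estimates pool one
observation per retained epoch (whole-epoch Hann FFT); epoch-level features
— required because classifier samples are single epochs — use 0.5-s Hann
segments at 50% overlap (seven observations per epoch), trading spectral
resolution for the existence of per-epoch estimates. Standard wPLI is used,
not the debiased-squared variant. Null wPLI is positively biased at small
observation counts (≈ (π n/2)^(−1/2) scale); the estimator shrinks toward 0
as observations accumulate, which the tests check as a monotone-median
property. Region-pair values are arithmetic means over the cross-region
channel pairs.

## Statistics

Student's pooled-variance two-sample t by default (Welch behind a flag),
two-tailed, sign convention HC − MDD so a patient increase is a negative t.
BH-FDR within the family actually passed (40 power features or 140
connectivity features). Features with zero variance in both groups are
flagged and assigned p = 1. χ² for sex is Pearson's without continuity
correction (df = 1). Clinical correlations are Pearson r in the patient
group only (controls have no severity score), two-tailed p from the
t-transform.

## Classification harness

Defaults: 90/10 splits repeated 10 times; standardization (z-score fit on
train), then the selector, then the model, all strictly inside the training
partition. The subject-grouped split allocates test subjects across classes
by largest remainder so the test share stays at 10% within one subject while
class proportions stay within ±1 subject; the epoch-stratified policy
(subjects may straddle partitions) is provided behind a flag because it is
one possible reading of participant-based stratification, but it leaks
subject identity and the tests document that it scores at least as high as
the grouped policy on data with subject-level random effects.

Selectors: SVM-RFE (recursive elimination by linear-SVM weights, one feature
per step, count chosen by 3-fold CV); L1-penalized logistic regression at a
CV-chosen penalty, keeping nonzero-coefficient features — if the CV ties at
chance (as it does on label-permuted data) and the winning penalty zeroes
everything, the selector falls back to the weakest penalty in the grid
rather than aborting, and errors only on degenerate input; PCA retaining
95% variance. Models use conventional fixed hyperparameters (k-NN k = 5;
RBF SVM C = 1, γ = 'scale'; Gini tree, unlimited depth; 100 gradient-boosted
trees of depth 3 at rate 0.1; Gaussian NB), all exposed through the config.
AUC uses the model's continuous score with MDD as the positive class. A
single-class test partition triggers a logged resample with the next seed.

The permutation test relabels **subjects** (all of a subject's epochs move
together — permuting epochs would break exchangeability under the grouped
split) and evaluates each of the B permutations with *exactly the same
statistic* as the observed value: the mean accuracy over `repeats` fresh
splits. Scoring permutations with a single split would give the null
statistic a higher variance than the observed one and inflate false
rejections. p = (b+1)/(B+1) never reaches 0; with B = 100 its floor is
1/101 ≈ 0.0099.

## Shapley attribution

A model-agnostic Monte-Carlo permutation estimator: for each explained
sample, random feature orderings are walked from a background row to the
sample, crediting each feature with the score change when it is switched in.
Background rows are cycled deterministically across draws, which makes local
accuracy — base value plus attributions equals the model score — hold
*exactly* (to float rounding) for any number of draws, not just in
expectation. Attributions are computed in the original feature space with
the scaler/selector inside the explained score function, so a PCA+k-NN
pipeline is still explained in terms of named features like LP-alpha.
Defaults: 100 background rows (or all training rows if fewer), 100–200
orderings, positive-class probability (or decision value) as the score. Ties
in the mean-|value| ranking break lexicographically by feature name.

## Orchestration and reproducibility

One root seed drives everything: per-subject generator seeds, split seeds,
permutation draws and Shapley orderings all derive from it through
`numpy.random.SeedSequence`, so `run_pipeline` is bit-reproducible —
the manifest records a SHA-256 per output file and reruns match exactly.
The pipeline configuration round-trips losslessly through YAML (region-pair
keys are serialized as `"roiA|roiB"` strings).

## Problem sizes

The full study scale is 10-min recordings at 1000 Hz. The package's own
checks run at a reduced scale chosen as the smallest regime where every
planted effect is still reliably detectable: 60-s recordings at 500 Hz and
15 subjects per group for recovery (≈30 epochs/subject, ~880 classifier
samples), 10 per group with 40-s recordings for attribution and null
calibration, and B = 100 permutations (B = 50 × 50 runs for the uniformity
check). Epoch arithmetic (300 epochs from 10 min) is verified once at the
full 1000 Hz scale. EDF output is plain 16-bit EDF with 1-s records and
per-channel symmetric physical ranges (~10⁻³ µV quantization at the
amplitudes generated); reading goes through MNE's EDF reader, which doubles
as an interoperability check.

## Known limitations

- Spherical-spline interpolation uses template electrode positions; with a
  digitized montage the geometry would differ slightly.
- Epoch-level wPLI from seven 0.5-s segments is strongly biased upward for
  delta (one usable bin at 2 Hz resolution); it is a classifier feature, not
  an unbiased connectivity estimate.
- The permutation test at B = 100 cannot report p below 0.0099; smaller
  p-values require more permutations.
- SVM-RFE with per-feature elimination is O(d²) model fits and becomes the
  grid's bottleneck on the 180-column set.
- The generator's group effects are stationary multipliers; analyses of
  dynamics (time-varying connectivity, microstates) are out of scope.
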