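# Methods

This note records the models, conventions and numerical choices behind
`bandpeak`, in the order data flows through the package.

## Synthetic trial model

A trial of task *t* on channel *c* is

    x_c(τ) = g_c · [ A_α J_α sin(2π f_α τ + φ_α)
                   + A_β1 J_β1 sin(2π f_β1 τ + φ_β1)
                   + A_β2 J_β2 sin(2π f_β2 τ + φ_β2) ] + s · n_c(τ)

with per-task amplitudes A (µV-like), frequencies f (f_α strictly inside
8–13 Hz, f_β inside (13, 30] Hz), per-channel gain g_c, and 1/f background
noise n_c of scale s. The jitter factors J ~ U[0.8, 1.2] and phases
φ ~ U[0, 2π) are redrawn per trial and shared across channels (one cortical
source seen by all electrodes); the noise is drawn independently per
channel. With `jitter=False` the factors are 1 and phases 0, making
noiseless trials exact sums of sines — useful as ground truth.

The 1/f noise is white Gaussian noise shaped in the frequency domain with
amplitude ∝ 1/√f for f ≥ 1 Hz and flat below 1 Hz, then divided by its
analytically expected standard deviation so that `noise_scale` is the
output std in expectation. This reproduces the qualitative low-frequency
dominance of resting EEG; it deliberately omits artefacts (eye blinks,
EMG), non-stationarity, inter-subject variability and volume conduction.
Passing tests on this generator therefore demonstrates correctness of the
*pipeline*, not expected accuracy on real recordings.

Default task profiles encode the phenomenon the features exploit: the alpha
peak is strongest at rest (A_α: RS 3.0 > LA 2.4 > RH/LH 1.8 > MA 1.5, all
near 10 Hz), and the motor imagery tasks have clearly reduced beta peaks
(0.6/0.45 vs ≈1.1/0.85 elsewhere — event-related desynchronization), with a
mild 1.15× contralateral central-channel gain for RH/LH. `noise_scale`
defaults to 1.0, which puts default-profile pairwise accuracies in the
90s rather than at ceiling. No quantitative amplitudes are published for
this kind of single-channel montage, so these values are free parameters
chosen once as a plausible operating point and kept fixed.

## Preprocessing

Filtering uses a 10th-order low-pass digital Butterworth at 50 Hz, designed
by bilinear transform with pre-warped cutoff, stored and applied as cascaded
second-order sections (a direct-form order-10 filter is numerically
fragile). The pass is **causal**, not zero-phase: phase is irrelevant to
the PSD features, and causality keeps epochs physically realizable. The
filter state is initialized to the step steady state of each channel's
first sample, removing the startup transient while remaining linear in the
input (a DC signal passes unchanged). The design gives −3.0103 dB at 50 Hz
and ≈69 dB attenuation at 100 Hz (fs = 512 Hz).

Segmentation drops the first 2 s (task preparation) of each 10 s trial and
splits the remaining 8 s into two 4 s parts, so 100 trials per task yield
200 epochs per class per channel, each of 2048 samples. If a user-supplied
duration does not divide evenly, the remainder is truncated from the trial
end with a logged warning.

## Spectral estimation

Welch's method with a 400-point periodic hamming window, 50% overlap
(hop 200), per-segment mean removal, one-sided per-Hz density scaling with
window power normalization, and trailing partial segments dropped. A 2048
sample epoch gives 9 averaged segments and 1.28 Hz bins. None of these
conventions affect the features' *ordering* information (the method only
compares PSD values within one spectrum), but they are fixed for
reproducibility and verified against an independently coded
mean-of-modified-periodograms reference to < 1e−10 relative error.

## Band-peak features

Alpha is the half-open interval [8, 13) Hz and beta the closed [13, 30] Hz,
so the shared 13 Hz edge belongs to beta only and no bin is counted twice.
A *local peak* is a bin strictly greater than both neighbors within the
band slice; plateau bins are not peaks. The extractor takes the top alpha
peak value (f₁) and the top two beta peak values (f₂ ≥ f₃), on a linear
scale — not dB, which would change classifier geometry. If a band contains
fewer interior peaks than needed (flat or monotone spectra), the selection
is padded with the largest remaining band bins, edge bins included, so the
vector is always 3-dimensional — classifiers need fixed dimensionality.
All value ties break toward the lower frequency; peak frequencies are kept
as metadata, not features. Two baseline extractors (time-domain
min/max/mean/sample-std, and trapezoidal alpha/beta band power) support
feature-set comparisons.

## Classification protocol

Per repetition: 50 epochs per class are drawn without replacement for
training, and 50 test epochs are drawn without replacement from the pooled
300-epoch remainder (each repetition independently redraws both). Features
are z-scored with the training split's mean/sd only. 100 repetitions give
the reported mean ± sd accuracy; sensitivity and specificity (positive
class = first task of the pair) come from confusion counts accumulated over
repetitions, and AUC is the mean of per-repetition AUCs.

LDA is the two-class closed form with equal priors (training splits are
always balanced): score(x) = wᵀx − ½wᵀ(μ₀+μ₁) with w = S⁻¹(μ₁−μ₀), where S
is the pooled within-class covariance plus a ridge of 1e−6·trace(S)/dim
(absolute floor 1e−12 when the scatter is exactly zero) so singular
scatters never crash; a zero score breaks toward the lower class index.
The SVM is scikit-learn's RBF SVC with C = 1 and σ set by the median
pairwise training-distance heuristic (γ = 1/2σ²) unless overridden — a
parameter-free default that adapts to feature scale; no grid search is
performed. ROC/AUC is computed in-package: the curve sweeps all distinct
score thresholds and the AUC is the rank-average Mann–Whitney statistic
(ties count ½), which equals the trapezoidal area under the tie-grouped
curve; scikit-learn's `roc_auc_score` serves only as a cross-check in
tests.

## Multiclass voting

Level 1: within each channel, all C(5,2) = 10 pairwise classifiers predict,
and the task with the most pairwise wins is the channel's label. Level 2:
channels vote for their labels weighted by their classification accuracy
(CA), estimated as the mean training-set accuracy of that channel's 10
pairwise classifiers (training-phase estimation; an unweighted plurality
mode is also provided since the weighting scheme admits two readings). All
ties break by the fixed enumeration RS < MA < RH < LH < LA. Test draws are
balanced across the five tasks (n_test_draw split evenly), making chance
exactly 20% and per-task accuracies comparable; the overall accuracy is
then the mean of the per-task accuracies.

## Seeding and determinism

A single global seed fans out to per-stage child seeds through
`SeedSequence([seed, crc32(stage_name), *indices])`, so stages and
(pair, channel, classifier) cells are statistically independent yet the
whole run — including every per-repetition draw — is byte-reproducible.
All derived seeds are reduced mod 2³¹.

## Problem sizes

The verification suite uses the full protocol for pairwise evaluation
(200 epochs per class, 50/50/100 subsampling) and 30 repetitions for the
multiclass checks; oracle-equivalence checks use 100 random epochs (Welch)
and 1,000 random spectra (peak search). These sizes make every Monte-Carlo
bound comfortably tight while keeping a full run fast on a single CPU.

## Known limitations

- The generator's stationary sinusoid-plus-1/f model omits artefacts,
  band-limited noise bursts and non-stationarity; accuracies obtained on it
  say nothing quantitative about real recordings.
- The peak-padding fallback makes degenerate (peak-free) spectra legal
  inputs, but the features are then band maxima, not true peaks.
- With 1.28 Hz bins the alpha band holds only 4 bins; oscillations closer
  than one bin are unresolvable by construction.
- EDF/BDF import is read-only, labels every window with one task, and
  requires the optional `mne` dependency.
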