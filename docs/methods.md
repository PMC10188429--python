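# Methods

This note documents the models, numerical choices and limitations behind
`eegvit`, in the spirit of a package methods appendix. Nothing here states
an empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Synthetic cohorts

**What is emulated.** Eight-channel limited-lead EEG at 250 Hz (one sample
every 4 ms) with a binary delirium label per recording, as produced by
rapid-response headband devices on critically ill older adults. The
delirium class carries the classic *slowing* signature — elevated delta
and theta power, suppressed alpha.

**Signal model.** Each channel is a sum of

- narrowband activity per canonical band (delta 0.5–3, theta 4–7, alpha
  8–12, beta 15–30, gamma 30–60 Hz; the upper gamma edge closes the
  physiologically open ">30 Hz" band for synthesis). Two synthesis modes:
  `sinusoid` (three equal-power sinusoids per band, frequencies uniform in
  the band, random phases — trivially verifiable with a periodogram, the
  default for raw profiles) and `filtered_noise` (complex-Gaussian DFT
  coefficients on the in-band bins — band-limited Gaussian noise whose
  envelope waxes and wanes on the ~1/bandwidth timescale, as real rhythms
  do; the default for cohort templates);
- an aperiodic 1/f² background (`pink_sd`, default 20 µV; exponent 2 in
  power, flattened below 0.3 Hz), the dominant non-rhythmic component of
  scalp EEG;
- white Gaussian noise (`noise_sd`, default 5 µV) for instrument noise;
- optional artifacts: coherent mains line noise (60 Hz — US clinical
  setting) and Poisson-timed broadband muscle bursts. Defaults off.

**Default amplitudes** (µV): control delta 20, theta 30, alpha 20, beta 5,
gamma 2 — a drowsy, sedated-ICU spectral profile in which diffuse theta is
prominent. The delirium template doubles delta and theta and halves alpha.
A second template pair (`delta_contrast_profiles`) differs **only** in
delta amplitude (×2); it is the cohort used to demonstrate the
window-length mechanism, because its class signal lives entirely below
3 Hz.

**Cohorts** draw subject-level heterogeneity log-normally around the
template: overall gain (log-sd 0.1), each band's amplitude (log-sd 0.1,
one factor per band shared across channels — people differ in spectral
profile), and both background levels (log-sd 0.45 — electrode impedance
and ambient artifact levels vary widely between sessions). Labels are
assigned to `round(n · fraction)` subjects and shuffled across ids.
Everything is reproducible bit-for-bit from one integer seed.

**What the generator does not emulate.** Forward-modelled head geometry
(channel correlations from volume conduction), non-stationary state
changes (sleep transitions, sedation boluses), device dropouts, and any
within-class clinical heterogeneity beyond log-normal amplitude scatter.
Passing tests on these cohorts show the pipeline recovers *band-power
class structure under realistic backgrounds and subject scatter*; they do
not show clinical-grade delirium detection.

## Why the short-window chance level is a calibrated property

The window-length experiment expects ~chance accuracy at 0.1 s slices and
high accuracy at 5 s. This is *not* automatic for an amplitude-contrast
generator: a ×2 delta-amplitude difference changes the variance
contributed by delta inside **any** window, however short, because the
in-window delta segment is a ramp whose slope scales with amplitude. With
constant-amplitude sinusoids and white noise only, a classifier reads this
ramp-to-texture ratio and scores far above chance at 0.1 s. Three
realistic ingredients suppress that leak: the stochastic envelopes of
`filtered_noise` synthesis (a short window sees one random envelope draw,
a long window averages many), the aperiodic background and its
between-subject scatter (class-common slow ramps), and prominent theta
(in a 0.1 s window a theta ramp is indistinguishable from a delta ramp,
while a 5 s image separates the bands spectrally). With all three, 0.1 s
windows sit at the edge of the 99 % binomial chance band while 5 s windows
stay well above 0.9. The margin is thin and seed-dependent: with only
twelve subjects and three held-out test subjects, a single unlucky subject
draw moves slice-level accuracy by several points; medians over five
replicates are reported for exactly this reason.

## Preprocessing

4th-order Butterworth band-pass applied forward–backward (zero phase;
effective order 8), defaults 0.1–40 Hz — the low cutoff is the common
clinical choice and retains sub-delta drift, the 40 Hz cutoff removes
line-noise and most EMG. Common-average reference. Epoching drops the
trailing remainder. ICA cleaning uses FastICA (negentropy-maximising
fixed point, unit-variance whitening, seeded); a component is rejected if
its plain (Pearson) kurtosis exceeds 10 — Gaussian background sits at 3,
spike artifacts far above — or if more than half its spectral power lies
above 30 Hz (EMG-like). On convergence failure the recording passes
through unmodified with a logged warning; this is common on synthetic
band-noise cohorts, whose sources are near-Gaussian and therefore poorly
identifiable — the artifact-rejection path is exercised with
super-Gaussian spike sources, where the fixed point converges. The
"uncleaned" analysis arm skips only the ICA stage.

The original analysis named none of these constants (filter cutoffs,
reference scheme, epoch length, rejection rules); all defaults here are
this package's own and are flagged as unverifiable against it.

## Slicing and splitting

`stride = max(1, round(n·(1−overlap)))` with half-away-from-zero rounding
(an epsilon guards binary-representation artefacts). Windows are half-open
`[origin, origin + n)` starting at multiples of the stride while a full
window fits: `count = floor((N − n)/stride) + 1`. Splits are grouped at
the subject level (test side ≈ `round(test_fraction · n_subjects)`
subjects, both classes on both sides, all of a subject's slices travel
together); balancing down-samples the majority class to the minority count
*after* splitting, independently per side, so test counts never inform
training. Desk-scale experiments keep at most 100 slices per recording
(uniform random subsample before splitting) so problem sizes stay
comparable across window lengths.

## Imaging

Corner-aligned separable bilinear interpolation: destination index `i` on
an axis of output length `M` maps to source coordinate `i(N−1)/(M−1)`, so
corners map to corners; the 2×2→3×3 upsampling case is oracle-tested
against the hand-evaluated interpolant. When an axis shrinks by more than
2× (e.g. 1250 columns → 64), a moving average of half the decimation width
is applied first — the antialiasing step library resizers perform — so
slow-wave structure survives decimation instead of being folded into alias
noise; pure upsampling is exact two-point interpolation. Intensities are
min–max normalised to [0, 1] per slice (constant slices map to 0.5).
Spectral images replace each channel by `log(1 + |X_k|)` of its one-sided
DFT before the identical resize/normalise step, so the two encodings
differ only in what the pixels mean. The frequency-domain rendering is
this package's reconstruction of a comparison arm described only at the
workflow level; reports label it as such.

## The Vision Transformer

Standard pre-norm ViT: flattened non-overlapping patches are linearly
embedded, a learned class token prepended, learned positional embeddings
added; each block applies layer-norm → multi-head scaled-dot-product
self-attention → residual, then layer-norm → 2-layer GELU MLP
(`mlp_ratio`× expansion) → residual; a final layer norm feeds a linear
head on the class token. Forward, backward (layer norm, softmax attention
and GELU derivatives by hand) and Adam (β₁ 0.9, β₂ 0.999, ε 1e-8) are
implemented directly on NumPy arrays; gradients are verified against
central finite differences in the test suite, and training is
deterministic given the seed.

Numerical choices: Glorot-scaled weight initialisation (at embed dim 64 a
fixed 0.02 standard deviation starves gradient flow); the classification
head starts at zero, so an untrained model is exactly at chance (initial
loss ln 2) and early updates shape the head before the trunk; inputs are
standardised with a scalar mean/sd estimated on the training set and
stored with the parameters (per-image standardisation would erase
mean-intensity information). Embedding dimension 512 at clinical scale
(divisible by 8 heads), `mlp_ratio` 4, no dropout, no pretraining, no
augmentation beyond window overlap. Exact probability ties at prediction
are broken toward the control class and flagged.

The *clinical preset* (224 px, patch 16, depth 12, heads 8, batch 64,
lr 1e-3, 5 epochs) is the full-scale configuration; the *desk preset*
(64 px, patch 8, embed 64, depth 2, heads 4, `mlp_ratio` 2, batch 32,
75 586 parameters) exists so the full experiment suite runs in minutes on
one CPU. From-scratch training is the implemented reading; whether the
original analysis fine-tuned pretrained weights is not stated anywhere and
cannot be reproduced either way.

## Experiments and evaluation

A condition is (slice length, overlap, encoding domain, cleaning arm).
The runner executes generate/load → preprocess (cached per arm across a
sweep) → slice → subsample → grouped split → per-side balancing → imaging
→ training → prediction, and reports the confusion matrix (delirium
positive), slice-level training/testing accuracy, and — as a clearly
labelled extension — subject-level majority-vote accuracy, because
90 %-overlapping slices from one subject are heavily correlated and
slice-level accuracy alone can overstate certainty. Epochs are fixed (5;
4 in the domain-contrast replica) rather than early-stopped. Every seed
(cohort, split, balance, subsample, model) is recorded in the report, and
re-running any condition reproduces every number bit-for-bit.

Desk-scale study sizes: 12 subjects (the published cohort scale; the
source reports twelve subjects in its results and thirteen participants in
its limitations — twelve is the default and the count is configurable),
60 s per recording, test fraction 0.25 (three held-out subjects), five
seeded replicates for the stochastic experiments, medians reported.

## Known limitations

- Slice-level accuracies on overlapping windows are optimistic for any
  deployment claim; the subject-vote score is the harder number.
- Three test subjects make single-replicate accuracies coarse (steps of
  ~1/n_test and strong subject-draw dependence); conclusions rest on
  medians across replicates.
- The "uncleaned" arm is supported, but the extreme accuracy reported for
  uncleaned clinical data elsewhere is unverifiable; reports from this arm
  carry an explicit caveat.
- FastICA on near-Gaussian synthetic sources frequently falls back to the
  identity; on real EEG with genuine artifacts the rejection path is
  expected to engage far more often.
- EDF support writes plain EDF (16-bit) and reads through mne; EDF+
  annotations are out of scope.
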