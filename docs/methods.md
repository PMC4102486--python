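# Methods

`nirsvig` implements a complete single-trial vigilance-decoding pipeline for
functional near-infrared spectroscopy (fNIRS): a forward simulator of a
global-local Stroop session with reaction-time-coupled hemodynamics, the
standard preprocessing chain (Butterworth low-pass, modified Beer-Lambert
inversion, per-run drift correction and z-normalization), a
finite-impulse-response GLM with RT parametric modulation, sliding-window
space-time support-vector regression of single-trial reaction times, and a
wavelet time-frequency variant of the decoding.  Because no recorded dataset
ships with the package, every analysis is validated by *parameter recovery*
and *null calibration* against the simulator's ground truth.

## Experiment and behavior model

A session has 6 runs of 60 trials (30 congruent, 30 incongruent, randomly
ordered per run).  The attention factor (global vs local letters) switches
between the first and second half of the session and, by design, influences
nothing — the analyses operate on condition-corrected RTs.

**Inter-trial intervals.** ITIs follow a truncated shifted exponential on
[7, 12] s.  The decay rate is solved numerically (Brent) so the truncated
mean equals 7.9 s, which makes the expected run duration 60 × 7.9 = 474 s
and the expected session 2844 s.  This is the unique one-parameter
exponential-decay law consistent with the range and mean simultaneously; a
requested mean outside (7, 9.5] s is rejected with the feasible interval in
the error message (9.5 s, the midpoint, is the uniform zero-rate limit).
ITIs are continuous; no display-refresh discretization is applied.

**Reaction times.**

    rt = rt_base + congruency_effect · [incongruent] + v(trial) + ε,
    ε ~ N(0, rt_noise_sd²)

with defaults rt_base = 550 ms, congruency_effect = 60 ms and
rt_noise_sd = 40 ms — typical global-local Stroop magnitudes.  `v` is the
slow "vigilance" fluctuation: by default a stationary AR(1) over the trial
sequence with coefficient 0.8 and innovation sd 30 ms (stationary sd
50 ms); a sinusoid-mixture alternative in absolute session time exists for
time-frequency experiments.  Correctness is Bernoulli per condition with
default error rates 2.75/180 (congruent) and 7.75/180 (incongruent), i.e.
per-subject expected error counts of 2.75 and 7.75 per condition and 10.5
overall across a session.  Missed/incorrect trials carry no RT but keep
their design slot.

**Mean correction.** For every (run, condition) cell the mean RT over
correct trials is subtracted, so corrected RTs average exactly zero per
cell and carry no congruency information; only fluctuations around the
cell mean — the operational vigilance measure — remain.  The operation is
idempotent and refuses cells with no correct trials.

## Hemodynamic forward model

**HRF.** A double-gamma kernel: gamma density with shape
`peak_delay/dispersion` (default 7/1, mode at 6 s) minus an undershoot
gamma (delay 16 s) scaled by 1/6, truncated to finite support [0, 30 s)
(the discarded tail is < 1e-6 of the peak; truncation keeps
non-overlapping trials exactly identical) and peak-normalized.  The family
is an implementation choice exposed in `SignalConfig`; nothing downstream
assumes this shape — the FIR GLM estimates it.

**RT coupling.** Each trial contributes
`(1 + coupling_beta · rt_corrected) · h(t − onset − latency_beta · rt_corrected)`
on responsive channels (default: every 4th of the 44 channels).  The
amplitude ledger `1 + coupling_beta · rt_corrected` is returned as ground
truth for recovery tests.  Defaults: coupling_beta = 0.002 per ms (≈ ±13%
amplitude over the typical corrected-RT range), latency_beta = 0 (off).
Latency coupling (slower responses peak later) exists because the
underlying phenomenon includes peak-latency shifts; it moves information
into higher frequencies (temporal fine structure), whereas amplitude
coupling is carried mostly by the response's low-frequency bulk.  HbR is a
mirrored copy of the HbO task component: scaled by hbr_ratio = −0.35 and
lagged 1 s, with independent noise.

**Noise.** Per channel: cardiac (1.1 Hz, amp 0.4), respiratory (0.3 Hz,
amp 0.15) and Mayer-wave (0.1 Hz, amp 0.1) sinusoids with channel-random
phases, a channel-random linear drift (slope sd 0.003 /s) and white noise
(sd 0.25), all in units of the unit-peak response.  What this emulates:
the dominant quasi-periodic physiological contaminants and slow
instrumental drift of optical recordings.  What it does not: 1/f
low-frequency spontaneous fluctuations, motion artifacts, scalp-vs-cortex
partial-volume effects, or spatially correlated noise — so passing tests
demonstrate correctness of the analysis chain under the modeled noise, not
expected effect sizes on real recordings.

**Optics.** The forward modified Beer-Lambert law maps concentration
changes to attenuation changes per wavelength:
`ΔA(λ) = [ε_HbO(λ)·ΔHbO + ε_HbR(λ)·ΔHbR] · d · DPF(λ)` with
source-detector distance `d` (44 channels, 2–3 cm, assembled from 16
sources × 16 detectors; scalp coordinates are out of scope).  Default
extinction coefficients (1/(mM·cm)) are standard tabulated values —
850 nm: 1.058 (HbO), 0.691 (HbR); 760 nm: 0.586, 1.548 — with DPF 5.8/6.4.
All correctness guarantees (round-trip identity, linearity) hold for any
nonsingular positive matrix; the constants only set units.  Concentrations
are reported as concentration × pathlength (mM·cm-equivalent), which
sidesteps the unknown absolute pathlength.

## Preprocessing

Order contract: low-pass filter the raw attenuation, invert the
Beer-Lambert system to ΔHbO/ΔHbR, then (for decoding only) per-run linear
detrend and z-normalization.  The FIR GLM consumes un-normalized
chromophore series and models drift with its cosine basis instead.

The low-pass is a 3rd-order Butterworth at 0.25 Hz.  Default phase mode is
zero-phase (forward–backward, `sosfiltfilt`), which preserves the latency
of the hemodynamic peak but squares the magnitude response; a causal
single-pass mode with steady-state initialization is provided, and the
closed-form magnitude reference used in tests is the analog Butterworth
formula on the bilinear-prewarped frequency axis (exactly the digital
filter's response).  The first/last 5 s are flagged in metadata as
edge-affected.  Channels that are constant or pure lines after detrending
are reported as errors by name, not silently zeroed.

## Analysis I: FIR GLM with RT parametric modulation

Per run, 12 event-related stick regressors (ER-HR) model the response
shape: bin k places a unit stick `k · 6` samples (0.96 s) after each
trial's onset sample (nearest-sample rounding, ties away from zero — the
convention that reproduces −5 s → −31 and 14.7 s → 92 samples at 6.25 Hz),
spanning 0–10.56 s.  Twelve parametric-modulation regressors (ER-PM) carry
the trial's mean-corrected RT at the same samples, correct trials only; 24
task regressors in total.  Drifts are absorbed by a discrete-cosine basis
with all periods above 128 s plus a per-run intercept.  Runs are stacked
with shared task columns and block-diagonal nuisance columns (run-wise
nuisance regression).  Ordinary least squares per channel; no
pre-whitening.  Group inference: one-sample t-test of each beta across
subjects, df = n − 1.  Sticks falling past a run's end are truncated with
a logged warning; modulators whose cell mean exceeds 1e-6 ms are rejected
(the table must be mean-corrected first); rank-deficient designs raise
with the collinear column names (e.g. all-zero ER-PM when every corrected
RT is zero).

## Analysis II: sliding-window space-time SVR

Windows of 7 samples move in steps of 3 from −31 to 92 samples (−5 s to
14.7 s) around onset: 40 positions.  Features per correct trial: both
chromophores × 44 channels × 7 samples = 616 values.  A linear-kernel
support-vector regression (C = 1, ε = 0.1; hyperparameters are documented
defaults, not claimed faithful to the original) predicts mean-corrected
RTs under leave-one-run-out (6-fold) cross-validation.  Features are
standardized with training-fold statistics only; the held-out run cannot
influence the model (property-tested by appending an outlier to the test
fold).  For the linear kernel the Gram matrix is precomputed with BLAS and
passed to the same libsvm solver — predictions are bit-identical to the
direct path and the fit is about twice as fast.  Accuracy per fold is the
Pearson correlation between predicted and actual RTs; correlations are
Fisher-Z transformed (atanh, |r| clipped at 1 − 1e-12), averaged per
subject over folds (undefined folds — e.g. constant test targets — are
logged and excluded), and tested against zero across subjects per window.
Windows are uncorrected at p < 0.05, mirroring the original analysis;
trials whose window crosses a run boundary are dropped with a logged
count.

A caveat that matters for calibration: with the default AR(1) vigilance,
the *previous* trial's response genuinely predicts the next corrected RT,
so above-chance pre-stimulus decoding is real carried-over information,
not leakage.  Chance-level-pre-stimulus checks therefore use the iid
configuration (`ar_coef = 0`) of the same process, for which no
pre-stimulus information exists by construction, and "significant
decoding" is assessed above chance (positive z), the direction the
original analysis tested.

## Analysis III: wavelet time-frequency decoding

Each preprocessed series is decomposed with a complex Morlet CWT
(`cmor1.5-1.0`; bandwidth and center frequency configurable) into 250
linearly spaced bands over 0.001–0.25 Hz (both spacing and family are
configuration choices; linear spacing matches a linear frequency axis).
The amplitude envelope (coefficient modulus) replaces the signal; features
are the window-*mean* envelope per channel (88 values), and
cross-validation, Fisher-Z aggregation and group inference are identical
to Analysis II, yielding a band × window accuracy map.  Bands slower than
one cycle per run are kept but flagged unreliable (edge-dominated).  The
filter bank is evaluated in chunks of scales sized to ~250 MB of envelope
memory so each run needs one FFT-based CWT call per chunk.

With the default design (ITI mean 7.9 s → trial rate ≈ 0.127 Hz) the map
of a coupled simulation peaks in the 0.1–0.15 Hz band a few seconds after
onset: the trial-locked response train concentrates single-trial amplitude
information at the design's repetition frequency.

## Problem sizes used by the test suite and acceptance script

All group-level checks run on a single CPU; sizes are the package's
standard analysis sizes:

* decoding calibration and power: 8 subjects × 6 runs × 60 trials, all 40
  windows, null (coupling 0) and coupled (coupling 0.005, iid vigilance)
  runs;
* GLM null calibration: 1000 noise-only channels across 8 subjects
  (12 000 bin-level group tests);
* cutoff sweep: 4 subjects, cutoffs {0.1, 0.15, 0.2, 0.25, 0.3} Hz,
  post-onset windows (2–9 s), amplitude + latency coupling
  (coupling_beta 0.002, latency_beta 0.006 s/ms) so the informative band
  extends above 0.1 Hz — the regime in which a 0.1 Hz cutoff is expected
  to cost accuracy;
* time-frequency map: 50 linearly spaced bands (0.001–0.25 Hz), 4
  subjects, window step 6.

## Numerical choices and degenerate inputs

* Onset-to-sample mapping: round half away from zero, everywhere.
* ER-PM of incorrect trials is zero; the ER-HR stick remains.
* atanh clipping at |r| = 1 − 1e-12; undefined fold correlations become
  NaN and are excluded from subject means with a warning.
* Group t-tests with zero between-subject variance: all-zero means give
  t = 0, p = 1 (exact chance); nonzero constant betas raise — a simulated
  group with literally identical subjects is a configuration error.
* Seed discipline: a master seed plus subject index feed
  `numpy.random.SeedSequence((master_seed, subject))`, so enlarging the
  group never changes existing subjects; identical config + seed
  reproduces every table bit-for-bit.
* Extinction matrices are rejected as singular below a relative
  determinant of 1e-12; zero-variance channels are reported by name.

## Known limitations

* The simulator's noise has no 1/f component and no spatial correlation,
  so absolute decoding accuracies are optimistic relative to real
  recordings; only orderings, calibrations and recovery properties should
  be read.
* SVR hyperparameters of the original analysis are unknown; C = 1,
  ε = 0.1 are fixed documented defaults.
* Weight-vector interpretation (activation-pattern transforms) is out of
  scope, as are optode localization, atlas lookup and motion artifacts.
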