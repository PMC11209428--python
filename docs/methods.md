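# Methods

`mrcpkit` implements an offline analysis pipeline for movement-related
cortical potentials (MRCPs): the slow negative EEG deflection that precedes
and accompanies a self-paced voluntary movement. The pipeline mirrors a
standard repeated-measures study design — three recording sessions of 100
self-paced ankle dorsiflexions each, with a 2-min idle recording per
session — and consists of five stages: EMG-based movement-onset detection,
MRCP morphology quantification, single-trial MRCP-vs-idle classification,
repeated-measures statistics, and a synthetic session generator that
provides ground truth for all of the above.

## Signal model and conventions

All amplitudes are in µV, all times in seconds from recording start, and
sample index = round(t · fs). The default sampling rate is 500 Hz. The EEG
montage is 11 channels of the 10-20 system (FP1, F3, Fz, F4, FCz, C3, Cz,
C4, P3, Pz, P4); the EMG is a single bipolar channel.

Epoch windows are half-open on the right, [t0, t1), so a 2-s epoch at
500 Hz holds exactly 1000 samples. The component measurement windows
relative to movement onset are:

| Component            | Window            | Convention   |
|----------------------|-------------------|--------------|
| RP (readiness potential) | [-2, -0.5) s  | half-open    |
| NS (negative slope)      | [-0.5, -0.1) s | half-open   |
| MP (motor potential)     | [-0.1, +0.1] s | closed      |

The MP window is closed so that it is symmetric about the onset sample.
Artifact rejection is strict: an epoch is removed only when some sample on
some channel of the stage's channel set satisfies |v| > 125 µV; a sample at
exactly ±125 µV is kept. The morphology stage scans all 11 EEG channels;
the detection stage scans its single surrogate channel.

## Filtering

All filters are Butterworth bandpasses applied forward-backward
(`sosfiltfilt`), giving zero phase distortion and an effective magnitude
response of |H(f)|². "Order" refers to the overall filter order; an
order-4 bandpass is designed as a 2nd-order prototype (scipy doubles the
order for bandpass designs). The bands are 20-40 Hz (EMG), 0.1-10 Hz
(morphology), and 0.1-30 Hz (detection). Filters are always applied to the
continuous recording before epoching, never per epoch, so filter
transients stay outside the epochs.

## EMG onset detection

Pipeline: bandpass (20-40 Hz), full-wave rectification, threshold crossing.
An onset is the first sample whose rectified amplitude exceeds the
threshold; further crossings within a refractory period (default 5 s, i.e.
half the nominal 10-s movement pacing) are suppressed. The threshold is
either supplied explicitly or derived from the first 10 s of burst-free
baseline as mean + 8·SD of the rectified filtered signal. The multiplier
follows from Rice's upcrossing rate for a 20-40 Hz process: a mean + 5·SD
threshold is crossed roughly twice per 100 s of burst-free noise, which
corrupts the onset count over a ~17-min session, while mean + 8·SD makes
false crossings vanishingly rare and still sits far below the bursts
(which are ~50× the baseline SD). A baseline whose SD exceeds three times
its robust (MAD-based) scale is rejected as containing burst activity.
Instead of an interactive plausibility check of the detected movements,
`interval_outliers` reports inter-onset intervals deviating more than 2 s
from the nominal pacing.

## Morphology

The continuous EEG is filtered to 0.1-10 Hz, cut into 3-s epochs (-2 to
+1 s around each onset; onsets lacking full context are skipped and
counted), artifact-rejected, and averaged pointwise (with per-sample
standard errors). The RP/NS/MP amplitudes are the means of the average
waveform over the windows above, reported for Fz, FCz, and Cz. No baseline
correction is applied; the 0.1 Hz high-pass handles drift.

## Single-trial detection

Pre-processing: 0.1-30 Hz bandpass on all channels, then a large Laplacian
spatial filter centered on Cz yielding one surrogate channel,
Cz − (F3 + Fz + F4 + C3 + C4 + P3 + Pz + P4)/8 (FP1 and FCz are unused).
MRCP epochs are the 2 s before each onset; idle epochs are drawn uniformly
at random from the pre-processed idle recording (redrawing any epoch that
fails the ±125 µV check, with a retry cap) until both classes have equal
counts.

Each epoch yields 29 features:

* **5 temporal** — means over the four 0.5-s sub-windows and the
  difference between the first-half and second-half mean;
* **23 spectral** — Welch power spectral density with 1-s Hamming segments
  at 0.5-s overlap (exact 1-Hz bins; three segments per epoch), evaluated
  at the integer frequencies 8-30 Hz;
* **1 template** — zero-lag cross-correlation with the mean of the
  MRCP-class training epochs, normalized to [-1, 1]
  (Σx·t / √(Σx²·Σt²); the unnormalized inner product is available via
  `normalize=False`).

The template is built from MRCP-class epochs only: averaging both classes
would cancel the deflection the feature is meant to capture. Normalization
is chosen for scale invariance since the sources give no convention.

Classification is leave-one-out cross-validation with three fixed
classifiers: random forest (512 trees, seeded; remaining hyperparameters
are scikit-learn defaults), LDA, and k-nearest neighbors (k = 5). For
every fold the template, the feature z-scoring, and the classifier are
recomputed from the training epochs only — the held-out epoch never
touches its own fold's model. z-scoring is applied for LDA and kNN
(distance/scale sensitive) and not for the forest; both choices are
config-exposed (`ClassifierSpec.standardize`). Features with zero training
variance in a fold are dropped for the standardized classifiers and
logged. Accuracy is the percentage of correctly classified folds.

## Statistics

Component amplitudes are analyzed with one-way repeated-measures ANOVAs
(session as the within factor, one test per channel × component);
accuracies with a two-way repeated-measures ANOVA (session × classifier).
The sums of squares follow the classical partition, so
SS_total = SS_subjects + SS_condition + SS_error holds to numerical
precision in the one-way case, and each two-way effect is tested against
its own subject-by-factor error term.

Sphericity is tested per effect with Mauchly's W (chi-square
approximation) at α = 0.05; when violated, the Greenhouse-Geisser epsilon
— computed from the orthonormal-contrast covariance, with the interaction
using the Kronecker product of the factor contrasts — multiplies both
degrees of freedom, which are then reported fractionally (e.g. "1.6,
40.5"). Epsilon is clipped to [1/(k−1), 1]. Effect size is partial η² =
SS_effect/(SS_effect + SS_error). A significant omnibus test is followed
by Bonferroni-adjusted paired t-tests (p_adj = min(1, p · n_pairs)). The
one-way implementation agrees with pingouin exactly and the two-way
epsilons with R's `car::Anova`; both serve as independent oracles in the
test suite, not as the implementation.

## Synthetic data generator

The generator emulates the study conditions so that every stage can be
verified against known ground truth. Per session (defaults in
parentheses): 100 movements at 10 ± 0.5 s intervals, a 12-s quiet lead-in,
an 8-s tail, and a 2-min idle block.

**MRCP waveform.** `make_mrcp_template` builds a piecewise-smooth waveform
over [-2, +1] s — a monotone cubic through plausible knots (slow early
negativity, steeper slope, trough at onset, return to baseline by +1 s) —
and then adds one smooth Hann bump per measurement window so the RP/NS/MP
window means equal the configured amplitudes exactly. The sources define
the components only by window means, not by shape, so the means are the
contract. Default amplitudes are the pre-intervention values
(Fz: −1.4/−6.5/−7.9, FCz: −0.5/−8.2/−10.3, Cz: −0.5/−9.0/−10.8 µV);
the study-level generator also carries the second-pre and post-intervention
columns. The three midline channels get their own templates; the other
eight channels carry the Cz waveform scaled by a fixed central-dominant
topography (0.75 fronto-central/central, 0.4 parietal, 0.1 frontal pole).

**Recovery-lobe calibration.** A 0.1 Hz 4th-order zero-phase high-pass is
not transparent to a 10-s-periodic train of negative deflections: removing
the DC and attenuating the 0.1 Hz fundamental biases the measured window
means by ~1.5 µV. The generator therefore adds slow positive "recovery"
lobes on [1.2, 6.9] s after each onset — strictly between movements,
outside every 3-s morphology epoch and 2-s detection epoch — whose
amplitudes are found per session by a small linear solve (six Hann lobe
trains, least-norm exact solution) such that the 0.1-10 Hz-filtered
session recovers the configured window means exactly. Physically this
plays the role of the inter-movement return to electrical baseline that
AC-coupled acquisition enforces in real recordings. Because the lobes
never overlap an epoch, raw epochs at the true onsets still average to the
injected template exactly.

**Background activity.** Per channel: Gaussian noise with a 1/f amplitude
spectrum (flat below 0.5 Hz; default SD 5 µV), plus amplitude-modulated
10 Hz alpha (3 µV) and 20 Hz beta (2 µV) oscillations whose envelopes vary
on a ~0.5-s timescale. The beta envelope is attenuated by 50% over
[-1.5, +1] s around each movement (event-related desynchronization),
which is what makes the spectral features informative. Blink artifacts —
400-ms biphasic transients, 200 µV peak at FP1 scaled by a
frontal-dominant topography — occur at a Poisson rate (default 5 per
session, prorated for idle blocks); only their property of exceeding
±125 µV matters downstream. The default noise SD is the declared SNR
calibration: it was chosen so that default-condition single-trial
classification lands in the ~80% accuracy regime (measured: RF 84%,
LDA 82-84%, kNN 83-84% on seed-1 sessions).

**EMG.** Baseline white noise (SD 1 µV) plus 20-40 Hz band-limited bursts
(50 µV, 0.5 s) at each true onset. The burst envelope rises as a raised
cosine over 80 ms — motor-unit recruitment in a ballistic contraction is
gradual, and a step-like attack would let the zero-phase detection filter
smear burst energy backwards, biasing detected onsets early by ~60 ms.
With the default envelope the median onset error is ~25 ms.

**Determinism.** Every random draw is traced to the config seed through
named `SeedSequence` children; identical config and seed give byte-identical
sessions. In the study runner, per-(subject, session) seeds are derived as
`SeedSequence([study_seed, subject, session])`, so a subject's data do not
depend on execution order. Between-subject variability is a single
multiplicative MRCP gain per subject (SD 0.2, clipped at 0.3).

## What the generator does not model

No biophysical forward model (dipoles, volume conduction): spatial
structure is a fixed weight vector, so spatial-filter performance on real
EEG is not established by these tests. No EMG physiology beyond the burst
envelope; no eye-movement artifacts other than blinks; no
non-stationarity across a session (fatigue, electrode drift); no
intervention pharmacology — session-to-session amplitude differences are
injected directly as per-session template amplitudes. Passing tests
therefore demonstrate correctness of the signal processing and statistics
under the stated signal model, not clinical performance.

## Problem sizes and numerical choices

The test suite and the acceptance script run everything at the study's
per-session scale (100 movements, 500 Hz, ~17-min sessions) where the
check concerns a printed count or a recovery tolerance; simulation-heavy
property checks (SNR monotonicity, label-permutation nulls, multi-seed
timing) use 10-40-movement sessions and 40-permutation batches, sizes at
which the binomial/Monte-Carlo error bars quoted in each test are still
decisive. The ANOVA type-I calibration uses 1000 null simulations at the
study's n = 26, k = 3. EDF export quantizes to 16 bits over a
per-channel symmetric range (4 significant digits), so round-trip error is
bounded by one quantization step; the delimited text format round-trips
float64 bit-exactly. Degenerate inputs fail loudly: empty recordings,
all-rejected epoch sets, zero-energy template correlations, singular
contrast covariances, and unsatisfiable idle-epoch requests all raise
`ValueError` with diagnostic counts.
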