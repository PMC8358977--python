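# Methods

This note documents the models, the numerical choices, and what the
synthetic data do and do not establish. Defaults quoted here are the
package defaults; everything is configurable.

## Synthetic EEG generator

The generator does not model acoustics or a forward head model. It models
the *statistical situation* the decoding analysis assumes: two long
sessions per subject (one per stimulus class) in which a class-specific
stimulus-locked response repeats at exactly 2 Hz inside structured noise,
with realistic contamination.

**Evoked templates.** The two classes are distinguishable by spectral
content and topography, which is all the classifiers need:

- *drum*: an ~80 ms damped oscillation (carrier ≈ 11 Hz, decay ≈ 22 ms) —
  a fast transient with alpha-range energy, maximal near the vertex;
- *syllable*: a ~300 ms Hann-windowed low-frequency burst (≈ 3.2 Hz) —
  delta/low-theta energy, more lateral topography.

Tiled at 2 Hz into a 2-s epoch, the syllable template carries > 10× the
drum's delta-band power and the drum > 3× the syllable's alpha-band power
(measured with the package's own band-power extractor). Both fit well
inside the 0.5-s inter-onset interval. Waveform and topography get a small
seeded per-subject jitter that never moves energy across bands. The
template shapes are calibration choices for a working synthetic benchmark,
not claims about infant neurophysiology.

**Background noise.** Per channel, 1/f-power spectrum (slope α = 1,
flattened below 0.3 Hz so multi-minute drift does not dominate), spatially
mixed through an exp(−d/0.5) kernel over a deterministic Fibonacci-spiral
sensor layout on the unit sphere (64 positions; channels 61–64 carry no
evoked response, mirroring an unused-channel block). Every channel is
scaled to a common RMS (default 20 µV).

**SNR.** `snr` is the ratio of template RMS (over its support, at the
best-coupled channel) to background RMS. Cohort default 0.6 with a
log-normal subject spread (σ = 0.3, unit mean): strong enough that most
subjects decode clearly above chance on short sessions, weak enough that
single epochs are noise-dominated. A dedicated high-SNR setting (snr = 2,
artifact-free) serves as the "this must work" calibration subject, and
snr = 0 as the null.

**Artifacts.** Two kinds, with ground-truth manifests for recovery tests:

- *bad channels* (default 2 per subject): alternately near-flat and
  high-variance traces. The set is drawn **once per subject** and applied
  to both sessions — both sessions come from a single net application, so
  their bad electrodes coincide. This matters: see "session fingerprints"
  below.
- *transients*: Poisson-placed (default 8/min) 150 ms Hann pulses at 12×
  background RMS on a localized 12-channel neighbourhood. At 8/min, the
  probability that a 2-s epoch contains a transient is ≈ 23%, which puts
  the improbable-epoch rate in the targeted ≈ 25% regime.

**Seeding.** One master seed fans out through `numpy.random.SeedSequence`
spawn keys per subject and session, so any subset of the cohort can be
regenerated bit-identically in isolation.

## Preprocessing

Fixed order: band-pass → drop unused channels → downsample → bad-channel
detection/interpolation → average re-reference → epoch → improbability
masking.

**Band-pass 0.5–45 Hz.** Zero-phase (forward-backward) 12th-order
Butterworth in second-order sections. The order is chosen so the
forward-backward pass leaves ≤ 10% amplitude at 50 Hz while the −3 dB
edges stay at the nominal 0.5/45 Hz; lower orders leak mains-band energy,
and narrow stopband designs (Chebyshev-II) only reach the same attenuation
by gutting the top of the passband.

**Downsampling to 100 Hz** uses polyphase resampling with its built-in
anti-alias filter; event indices are rescaled and rounded to the nearest
sample.

**Bad channels.** Two statistics per channel, both z-scored across
channels, flag at |z| > 2 (single pass, not iterated):

- sample excess kurtosis (normal → 0);
- improbability: the negative mean log-density of the channel's samples
  under a Gaussian KDE pooled over all channels (evaluated on a 512-point
  grid and interpolated; deterministic strided subsampling caps cost).

The threshold is two-sided deliberately: a flat channel sits *at the mode*
of the pooled amplitude density, so it is an improbability low-outlier and
would be invisible to a one-sided rule. Flagged channels are replaced by
the unweighted mean of their 4 nearest non-flagged neighbours (Euclidean
distance between sensor positions). Note that a *relative* 2-SD criterion
across 60 channels flags ~2–3 channels even on clean data by construction;
the operative specificity bound is a ≤ 10% false-flag rate.

**Per-subject (joint) channel assessment.** `preprocess_subject`
concatenates a subject's two sessions before detecting bad channels and
interpolates the *same* set in both. Assessing each session separately
would interpolate different channel sets per stimulus class — and since
class and session coincide in this design, that stamps every epoch with a
session fingerprint that a classifier exploits: with per-session
assessment, a zero-SNR subject "decodes" at AUC ≈ 0.8; with the joint
assessment it sits at chance. Single-session use remains available via
`run_preprocessing`.

**Epoching.** Non-overlapping 2-s windows cut to stimulus onsets
(half-open [onset, onset + 200) at 100 Hz), label inherited from the
session, trailing partial window dropped. At 2 Hz each epoch contains
exactly 4 beats.

**Improbable epochs.** For every channel, an epoch's score is the negative
mean log-density of its 200 samples under that channel's across-epoch
amplitude KDE (pooled over the subject's epochs). Scores are centred per
channel with median and 1.4826·MAD — a consistent SD estimate that a
~25% contaminated minority cannot inflate to mask itself. An epoch is
flagged when any channel exceeds z_single = 6 or the channel-mean exceeds
z_all = 4. The thresholds are calibration choices with a derivation: an
"any of 60 channels above z" rule needs a per-channel tail probability
below 0.05/60 ≈ 0.00085 to keep false flags under 5%, which even exactly
normal scores only reach near z ≈ 3.3 — and these scores are right-skewed,
pushing the required robust-z threshold to ≈ 6. Measured on default
synthetic sessions: rejection rate 23–27%, transient-epoch sensitivity
93–96%, false flags ≈ 0–1%. Epochs are masked, never dropped, so the
clean and all-epochs views are two selections of one object.

## CNN

Architecture (input 60 × 200): 1×4 temporal convolution, 12 filters, no
activation → 60×4 spatio-temporal convolution over the 12 maps, ELU →
1×4 max-pool (stride 4, floor) → flatten (576) → dropout 0.3 → dense 32,
ELU → dense 1, sigmoid. Shape chain
60×200 → 60×197 → 1×194 → 1×48 → 576 → 32 → 1; parameters
60 + 34,572 + 18,464 + 33 = 53,129, and the closed forms
(filters·kernel·in_maps + filters; units·inputs + units) are asserted
against the allocated weights in the tests.

Implementation is plain numpy with explicit analytic backprop (verified
against central finite differences to ~10⁻⁸ in float64) and a hand-rolled
Adam. The convolutions are evaluated as batched matrix products over
sliding windows (time-major layout), which keeps a forward+backward batch
of 32 under 100 ms on one CPU. Training is fully seeded: weight
initialisation (Glorot uniform), shuffling and dropout masks all derive
from the config seed, so identical configs give identical histories.

Choices where the design was open:

- one sigmoid output unit; two-digit one-hot codes are presentation only;
- min-max normalisation to [−1, 1] uses the global min/max of the
  (training) dataset, frozen and applied to test folds — preserving
  inter-epoch amplitude relations rather than normalising per epoch;
- class weights N/(2·N_c) multiply the per-sample loss;
- the reference protocol trains a fixed 25 passes; early stopping
  (validation AUC, patience 6, best-weights restore) is available behind a
  flag for model-development workflows;
- max-pool of length 194 with width/stride 4 floors to 48.

## SVM path

Per 2-s epoch and channel, a Hann-windowed periodogram (0.5 Hz bins) is
summed over δ [1, 4), θ [4, 8), α [8, 12) Hz — half-open bands so the 4
and 8 Hz bins are not double-counted — giving 3 × 60 = 180 features.
Because band powers are heavy-tailed, features are log-transformed and
z-scored on training statistics; PCA (30 components) is fit on the
training fold only; the classifier is a linear-kernel SVC with C = 1.
All statistics are frozen on the training fold — permuting test labels
cannot change any fitted parameter, which the tests assert.

## Evaluation

- **Folds**: shuffle, split into k = 5 groups differing by ≤ 1 in size,
  not stratified (matching the literal protocol); a draw that leaves a
  test fold single-class is redrawn with a fresh seed and logged.
- **AUC**: Mann–Whitney rank formulation, ties ½; the tests verify exact
  agreement (10⁻¹²) with trapezoidal ROC integration on random tied
  fixtures. The subject score is the *mean of fold AUCs* (sample SD over
  the 5 folds); a pooled-prediction AUC is also recorded.
- **Significance**: exact binomial upper tail, no approximation. c* is
  the smallest count with P(X ≥ c* | n, ½) < α; scores strictly above
  100·(c*−1)/n are significant (strict inequality). For n = 100:
  58% at α = 0.05, 68% at α = 10⁻⁴.
- **Robustness**: the identical CV protocol run twice per subject, clean
  vs all-epochs; degradation = mean AUC difference.
- **Rank-sum test** (two-sided) for site comparisons: normal
  approximation with tie correction when both groups have ≥ 8 values,
  exact enumeration of the (tied) rank-sum distribution otherwise. W is
  the smaller group's rank sum. (The test is a rank-sum — i.e. unpaired —
  test; a *signed*-rank test would require pairing.)

## Study sizes used in tests and scripts

Full-length sessions are 2000 repetitions (≈ 16 min); the package's own
analyses scale session counts down while keeping all per-time-unit
conditions (stimulus rate, SNR distribution, artifact rate and amplitude)
at their defaults: the cohort runs use 160 repetitions (80 s, 80 epochs
per subject), the calibration subjects 240–400 repetitions, and cohort CNN
training 12 passes instead of 25. The acceptance script generates one
full-length 2000-repetition session to verify event and epoch geometry at
the native scale. The zero-SNR null subject is generated artifact-free:
it measures stimulus decodability at chance, uncontaminated by the
(separate, well-documented) below-chance bias that cross-validating null
data with structured outlier epochs induces.

## What passing on synthetic data does and does not show

The generator guarantees the *existence* of a class difference with known
SNR and known contamination, so the tests establish that the pipeline
recovers signal when it is present, sits at chance when it is absent,
recovers injected contamination, and reproduces the qualitative
robustness ordering (band-power features are corrupted by high-amplitude
transients in a way raw-epoch convolutional features are not). They do not
establish infant-EEG effect sizes: real evoked responses are weaker, less
stationary and less stereotyped than the templates, real artifacts are
richer than flat/noisy channels and Hann pulses, and real sessions carry
state changes (sleep/wake) the generator omits. Absolute AUC values on
synthetic cohorts are therefore not comparable to real-data values.

## Known limitations

- The improbability statistics use KDE with deterministic subsampling;
  extremely short sessions (< 10 epochs) are rejected rather than scored.
- Bad-channel detection is a single pass; a channel that is bad only for
  part of a session is better caught by the epoch-level mask.
- No artifact *correction* (ICA, wavelets) is implemented — by design,
  the pipeline only removes or masks.
- EDF export is not implemented (no writer dependency); the HDF5 container
  plus TSV event sidecar is the canonical on-disk form, with EDF ingestion
  available when mne is installed.
- The CNN is CPU-oriented; there is no GPU path.
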