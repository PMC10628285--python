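# Methods

`microspeech` re-implements a complete micro-electrocorticography (µECoG)
speech-decoding analysis as a tested, reusable pipeline.  Real recordings
of this kind are restricted-access patient data, so the package ships a
synthetic-recording generator with known ground truth; every analysis
stage is validated against that ground truth or against closed-form
oracles.  This note documents the models, the conventions chosen where
the methodology is genuinely open, and what the synthetic validation
does and does not establish.

## The speech task and its event model

The task is auditory non-word repetition: 52 unique tokens — 26
consonant-vowel-consonant (CVC) and 26 vowel-consonant-vowel (VCV) —
built from 9 phonemes (vowels /a/, /ae/, /i/, /u/; consonants /b/, /p/,
/v/, /g/, /k/), presented in blocks of 52 shuffled tokens (three blocks
by default).  Trials last 3.5–4.5 s: a ~0.5 s auditory stimulus, a
response latency drawn uniformly from 0.7–1.5 s, a spoken utterance of
0.3–0.7 s, and a 250 ms inter-trial gap.  Token inventories are sampled
so that each phoneme's usage per slot is as even as possible (greedy
least-used selection); without this, some phonemes appear in only a
couple of tokens and positional label marginals become so skewed that a
majority-class predictor beats nominal chance — an artifact a designed
phonotactic inventory avoids.

All event times are seconds from recording start; every analysis window
is half-open `[t0, t1)`.

## Synthetic recordings

`synthesize_recording` renders, at 2 kHz by default (20 kHz-style rates
are supported; 2 kHz matches the post-decimation rate the analysis
assumes):

* **Background**: per-channel 1/f ("pink") noise (Kellet IIR
  approximation), spatially mixed across the lattice with a Gaussian
  kernel of length `noise_corr_length_mm` (default 1.2 mm, unit-power
  rows), plus a common-mode pink component that common-average
  referencing removes.  Default RMS 10 µV.
* **Evoked activity**: each phoneme is a sub-source offset ~1.5 mm from
  its articulator-class centre (low vowels, high vowels, labials,
  dorsals — four Gaussian spatial profiles of width `source_sigma_mm`,
  default 2.5 mm, placed at fixed fractions of the array extent).  Each
  event contributes an amplitude-modulated 70–150 Hz narrowband noise
  carrier: a raised-cosine envelope that rises `onset_lead_s` (default
  0.3 s) before the first phoneme's onset, per-position bumps at each
  phoneme onset, and a fall by utterance offset.  Event amplitudes carry
  lognormal (30%) trial-to-trial jitter; without it, distant
  co-activating sources correlate across trials and the envelope
  correlation-versus-distance curve is not monotone.  Carrier amplitude
  is calibrated to the background in-band RMS so that evoked SNRs land
  in the low-dB range reported for this kind of surface recording
  (roughly 1–4 dB per electrode at `source_gain = 1`).
* **Audio**: a microphone track with a 220 Hz stimulus tone and a
  speech-shaped (60–260 Hz band-limited noise) response burst per trial.
  The burst is deliberately non-tonal: tonal response audio creates a
  ridged audio-spectrum correlation profile that biases the
  contamination statistic even without leakage.
  `inject_contamination` adds band-passed, scaled audio to every neural
  channel (`leak_gain` × mean neural RMS).

All randomness flows from a single integer seed through
`numpy.random.SeedSequence` child streams (task, carriers, background,
audio), so a seed fully determines a bundle.

What the generator does **not** emulate: biophysical cortical dynamics,
realistic speech acoustics, co-articulation beyond overlapping envelope
bumps, non-stationary noise, electrode drift, or behavioural errors.
Passing tests therefore demonstrate that the *analysis chain* is
correct and sensitive under the assumed signal structure — not that the
same effect sizes would be observed in patient recordings.

## Preprocessing conventions

* **Channel QC**: exclude channels with impedance above 1 MOhm, or with
  `log10(RMS)` deviating from the channel median by more than 3 median
  absolute deviations.  The "3 × log-RMS" criterion in the source
  methodology is ambiguous; the MAD form is robust and scale-free, and
  the factor is configurable.
* **Referencing**: common average over included channels, subtracted
  from all channels.
* **Epoch rejection**: a trial is dropped when any included channel's
  within-trial RMS exceeds 10× its whole-recording RMS.  Because the
  artifact also inflates the whole-recording RMS, the attainable ratio
  is bounded by √(recording length / trial window); the 10× threshold
  is therefore only meaningful on recordings much longer than ~100
  trial windows, which full sessions are.
* **High-gamma envelope**: 8 log-spaced sub-bands on 70–150 Hz with
  bandwidth proportional to centre frequency (adjacent bands touch at
  geometric midpoints, raised-cosine edges, zero-phase frequency-domain
  filtering), analytic-signal magnitude per band, averaged, decimated to
  200 Hz (polyphase anti-aliasing), then normalized per electrode as
  `(x − µ)/µ` against the mean over 500 ms pre-stimulus baselines pooled
  across trials.  Subtract-and-divide makes values read as fractional
  change and renders the pipeline invariant to amplifier gain.
  Normalization follows decimation.
* **Low-frequency signal**: zero-phase FIR band-pass 1–30 Hz, decimated
  to 200 Hz, baseline mean-subtracted only (values stay in µV).

## Spectral metrics

Trial-averaged multitaper spectrograms use 500 ms windows, 50 ms steps,
and a 10 Hz total smoothing bandwidth (time-bandwidth 2.5, 4 tapers);
each electrode/frequency is divided by its mean pre-stimulus baseline
PSD before trial averaging.

The evoked SNR (ESNR) is `20·log10` of the baseline-normalized power
ratio aggregated over −0.5 to 0.5 s and 70–150 Hz.  The default
aggregates by the **mean** over time-frequency bins, so a flat ratio of
1 reads exactly 0 dB; a literal bin-**sum** convention (which depends
on bin counts and is nonzero for null data) is available via
`convention="sum"`, and the dB multiplier is a parameter for readers
who prefer the power (10·log10) scaling.

Electrode significance uses a one-sided response-vs-baseline permutation
test (default 10,000 iterations, within-trial label swaps implemented as
sign flips of per-trial differences, add-one p-values) with
Benjamini–Hochberg FDR at 0.05.  The temporal-cluster extension
thresholds the per-timepoint z of the same differences (z > 1.645),
scores contiguous runs by summed statistic, and compares against the
max-cluster-mass null from the same sign flips, yielding cluster onsets
and durations.

The acoustic-contamination audit computes short-time power envelopes
(200 ms Hamming windows) per frequency bin for the microphone and every
neural channel, correlates all audio×neural bin pairs over time, and
tests the mean diagonal on 70–150 Hz against shuffles of the neural
frequency bins **within that band** (10,000 draws, FDR-corrected).
Restricting the shuffle to the band is deliberate: utterance-locked
neural activity legitimately co-modulates with the audio envelope at
all frequencies, and an all-bin shuffle would flag that biology as
contamination; only the bin-exact diagonal structure characteristic of
electrical leakage survives the within-band null.

## State space and spatial subsampling

Trials × (electrode·time) matrices are column-centred and decomposed by
economy SVD (the explicit feature covariance is never materialized; its
eigenvalues are the squared singular values over n−1).  The minimal
leading set explaining 80% of variance is retained and embedded in 2-D
by Barnes-Hut t-SNE (perplexity 30, auto-lowered with a warning when
trials ≤ 3·perplexity).  Cluster quality is summarized by the silhouette
ratio (fraction of trials with positive silhouette) and score (mean over
positive-silhouette trials), with a label-shuffle chance level (1000
permutations).  Silhouette can be computed on the t-SNE coordinates
(default), on the top-2 PCs, or on all retained PCs.

Spatial subsampling draws n electrodes by dart-throwing with minimum
distance `r = 2·sqrt(X·Y/(n·3.5))` (the 3.5 factor is applied as given),
relaxing r by 5% per failure round up to 10 times with a logged warning;
the effective pitch of a sample is `sqrt(X·Y/n)` with X, Y the array
footprint (rows·pitch × cols·pitch — this convention makes the full
8×16 array at 1.33 mm return exactly 1.33 mm).

**Known limitation**: with smooth Gaussian sources, neighbouring
electrodes are largely redundant, so the *unsupervised* silhouette of
the state space barely changes under electrode subsampling even though
*supervised* decoding accuracy clearly degrades.  The package asserts
the decoding-based resolution effects on synthetic data and only the
structural contract of the silhouette-vs-resolution analysis; observing
a silhouette decline requires data whose fine spatial scales carry
independent information, as real recordings do.

## Linear decoding

`SVDLDAClassifier` centres and SVD-compresses the training fold, selects
the retained-component count by an inner stratified cross-validation
grid search over cumulative-variance targets (20 inner folds by
default), and fits a pooled-covariance LDA on the scores (SVD solver;
shrinkage LDA as fallback for singular within-class covariance).  Test
trials are projected with the training-fold mean and basis — no
normalization, decomposition, or selection ever sees test data, which a
dedicated test asserts.  The outer loop is 20-fold stratified CV
(reduced with a warning when a class has fewer members); accuracy is
pooled over outer test folds and compared to 1/n_classes with the exact
one-sided binomial tail.

Phonological error maps the row-normalized confusion matrix C onto the
Hamming distance matrix D: `e = (1/n)·Σ_ij ½·C_ij·D_ij` bits (the 1/9
prefactor generalizes to 1/n beyond the 9-phoneme task).  The shipped
17-feature table is a constrained reconstruction (see its file header):
feature assignments start from canonical SPE-style values, class and
vowel-place features held fixed, adjusted so the derived distances
reproduce the published pairwise anchors — d(p,b)=1, d(p,g)=5, maximum
9 at (p,i), uniform-confusion chance error 2.42 bits.  It lives in a
CSV so it can be corrected without code changes.

Articulator maps score each electrode by one-vs-rest ROC-AUC of its
**mean-envelope activation** per articulator (univariate decoding
values).  An alternative scoring from the per-electrode 4-way SVD-LDA
posteriors is available (`score="lda"`), but posteriors also encode
evidence *against* a class, so electrodes near a different articulator's
source also exceed 0.5 and the map blurs; the activation score recovers
planted source centroids to well under one electrode pitch, the LDA
posterior score does not.  Contours are the top decile of electrodes
(`ceil(0.1·n)`), centroids AUC-weighted contour means, areas contour
count × pitch² (a deliberately simple, monotone convention; polygon
areas depend on geometry choices).

Temporal decoding trains and tests an SVD-LDA per 200 ms segment (10 ms
steps over ±1 s around utterance onset — 181 segments at the reference
grid; tests use 50 ms steps).  Spatial sweeps: *resolution* (Poisson-
disc subsamples per electrode-count fraction), *coverage* (all
rectangular subgrids of given dimensions), and *contact size* (raw
voltage averaged within k×k blocks — simulating 200 µm up to several-mm
contacts — then HG extraction and decoding), with the 95%-of-full-array
threshold reported.  N-way sweeps average over all (or a sampled subset
of) C(9, N) class subsets and interpolate the spacing reaching 90%/95%
of full-array accuracy.

## Sequence decoding

The sequence model maps the 1 s utterance-centred HG window
(trials × electrodes × 200 samples) to the 3-phoneme sequence:

1. a **linear temporal convolution** with kernel width = hop = 50 ms
   (at 200 Hz: non-overlapping 10-sample frames, so 20 frames), no
   nonlinearity;
2. a **bi-directional LSTM encoder** (single layer); final hidden and
   cell states of the two directions are averaged (averaging both
   states is the default; hidden-only is switchable);
3. an **LSTM decoder** initialized with the encoder state, fed the
   one-hot previous phoneme — ground truth during training (teacher
   forcing), its own greedy argmax at generation — with a dedicated
   start token (one extra one-hot slot) at position 1, and a dense
   softmax head per position.

Training minimizes mean categorical cross-entropy plus an L2 penalty on
the convolutional and recurrent weights (not the softmax head), with
full-batch Adam at learning rate 1e-3 for a fixed 800 epochs (no early
stopping, no gradient clipping).  Hyperparameters (kernels 8–64, units
16–256, L2 1e-5–1e-1 log-uniform) are tuned by random search (200
combinations, 10-fold CV, 3 repeats) on the 80% training split.

The implementation is a compact numpy LSTM stack over a small
reverse-mode autodiff tape (`microspeech._autodiff`); it is float64,
single-threaded, and bit-reproducible for a fixed seed, and its
gradients are verified against central differences in the test suite.

The comparison harness against the linear decoder mirrors the intended
contrast: linear decoders need explicit phoneme onsets, so the test
jitters the onset *annotations* by ±150 ms (annotation noise; the
underlying sources follow the true onsets) while the sequence model
reads only the utterance-aligned window.  Under that regime the
sequence model's mean test accuracy is at least the linear decoders'
(median over seeded sessions).

## Problem sizes and test-time choices

Library defaults keep the reference analysis values: 20 outer/inner CV
folds, 10,000 permutations/shuffles, perplexity 30, 50 Poisson-disc
samples, 800 epochs.  The test suite exercises the same code at reduced
sizes of its own choosing: 1–2 task blocks of shortened trials
(2.2–2.6 s), 4×4 to 8×8 arrays for Monte-Carlo properties (the full
8×16 where the layout matters), 3–5 seeds per recovery property,
500–2,000 permutations, and 60–300 epochs for the sequence model.
Chance calibration subsamples trials to equal class counts (540
balanced trials from a 12-block session) so that permuted-label
accuracy is compared against the exact binomial band around 1/9 rather
than a majority-class base rate.
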