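# Methods

`worddecode` implements a complete single-trial EEG decoding pipeline for a
bilingual word-listening design, together with a synthetic-data generator
that emulates the experiment closely enough that every stage of the
pipeline can be validated against known ground truth.

## The emulated experiment

Sixteen native Dutch (L1) listeners, proficient in English (L2), hear four
monosyllabic animal nouns in both languages ("stier/bull", "eend/duck",
"paard/horse", "haai/shark"), each spoken by three female speakers, while
62-channel EEG is recorded at 250 Hz. A session has 8 runs of 2 blocks
(one per language; odd runs start with the English block). Each block
contains 24 animal trials (6 repetitions x 4 nouns; every word x speaker
stimulus exactly twice) and 12 non-animal target trials requiring a button
press, with onsets jittered uniformly 3.7–4.3 s apart. Over the session
every animal noun occurs 48 times per language. Non-animal trials keep the
listener attending but are excluded from analysis. Epochs span −1000 to
+1000 ms around word onset (half-open sample window, 500 samples), with
baseline correction over −1000..0 ms.

## Synthetic data model

Each animal trial is

```
x(c, t) = n(c, t) + a_w · W_wordform(c, t) + a_s · S_speaker(c, t) + a_c · C_concept(c, t)
```

where `n` is spatially mixed 1/f background noise (per-channel RMS
`noise_scale`, default 10 µV; exponent 1) and each component is a fixed
smooth random channel topography times a Hann-enveloped low-frequency
carrier (defaults 4 and 6 Hz, i.e. below 12 Hz where slow oscillations
dominate speech-evoked EEG):

* **word-form component** — one pattern per word form (8), *shared across
  speakers*, supported on 50–620 ms. This makes speaker-invariant
  within-language decoding possible.
* **speaker component** — one pattern per speaker (3), identical for all
  words; informative about the speaker only, so leave-one-speaker-out
  cross-validation cannot exploit it for word discrimination.
* **concept component** — one pattern per concept (4), *shared by the two
  translation-equivalent word forms*, supported on 500–650 ms. This is
  the only signal that can transfer across languages.

Patterns are fixed within a subject and redrawn across subjects; all
randomness derives from one master seed through `SeedSequence` splitting
(schedule, per-subject patterns and noise use disjoint streams), so
cohorts are bit-reproducible and the same schedule is shared by all
subjects of a cohort.

Default amplitudes (0.30 µV each against 10 µV noise) were calibrated once
so that, at the full design, the within-language accuracy time course
peaks at ~0.53 and across-language accuracy reaches ~0.51 in the concept
window — the range typically observed in single-trial EEG word decoding.
They are configuration values, not constants.

What the generator does **not** emulate: real scalp topographies or
anatomy (topographies are smooth random vectors), latency jitter of
components across trials, eye/muscle artifacts (only optional amplitude
outliers for testing rejection), stimulus acoustics, and any overlap
between consecutive trials in the epoched route. Passing tests therefore
demonstrate that the *pipeline* recovers what was embedded under realistic
noise; they do not certify effect sizes on real recordings.

## Preprocessing

Zero-phase (forward–backward) Butterworth band-pass, default 0.1–100 Hz,
order 4 per direction; zero-phase filtering is required because the
decoding claims are about latency. Epoching uses the half-open window
convention stated above; events too close to a recording edge are dropped
with a warning. Artifact handling is deterministic peak-to-peak rejection
(default 150 µV): independent-component-based correction of stereotyped
artifacts is out of scope because it requires manual component
categorization. The exact filter design for the band-pass is not critical;
any stable zero-phase design with a cutoff well below Nyquist passes the
same tests.

## Univariate analyses

The ERP is the trial-averaged response with SEM. The ERSP is computed with
a Hanning-tapered sliding FFT filter bank: 30 linear bins 1, 3, …, 59 Hz
(2 Hz steps), power expressed as `10·log10(P / P_baseline)` with the
per-frequency baseline mean taken over −1000..0 ms. The taper length is
250 ms, a compromise between resolution at the 1 Hz end and temporal
resolution; window length and overlap (every sample) are free parameters
of this package. Group statistics are two-sided Wilcoxon signed-rank tests
per point against baseline, Benjamini–Hochberg corrected at 5%.

## Decoding

All classifications are binary (chance 0.5) with features = all channels ×
the samples of a 40 ms sliding window (10 samples at 250 Hz; step 1 sample
by default, configurable), flattened and z-scored with training-set
statistics (zero-variance features are left unscaled; the bias feature
covers them).

* **Within-language**: for each language and word pair, train on two
  speakers (32 trials/word at full design), test on the held-out speaker
  (16 trials/word); average over 6 pairs × 2 languages × 3 folds.
* **Across-language**: for each concept pair, train on one language's word
  forms (48 trials/word), test on the translation equivalents of the other
  language; labels are carried by concept; average over 6 pairs × 2
  directions.

The classifier is an L2-regularized hinge-loss linear SVM (C = 1, at most
15 000 passes, dual-gap tolerance 0.01) solved by dual coordinate descent
with the bias as an augmented constant feature. It is compiled with numba
because a full simulation study performs millions of fits on ≤ 100-sample
problems, where estimator-API call overhead dominates arithmetic; the test
suite verifies prediction and weight agreement against scikit-learn's
`LinearSVC(loss="hinge")` on the same problems. Decision ties (score
exactly 0) deterministically go to `class_a`. Regularization is fixed (no
inner cross-validation), matching common practice when no hyperparameter
search is reported.

### Permutation and group inference

Per-subject significance uses a label-permutation null (default 200
permutations) with the add-one estimate `p = (1 + #{null ≥ obs}) / (1 + n)`.
Each permutation iteration draws **one coherent relabeling** of the trials
— concept labels shuffled within each language (across mode), word-form
labels shuffled within each language × speaker stratum (within mode, so
every fold keeps its class balance) — rebuilds all pairwise tasks from it,
and reruns the full task-averaged analysis. Training labels only; test
labels stay fixed, so the null probes the learned mapping. Permuting each
task independently instead would decorrelate the overlapping pairwise
tasks and shrink the variance of the task-averaged null: we measured a
per-subject false-positive rate of ~13% at nominal 5% on pure-noise data
with independent per-task permutations, against ~5–9% with coherent
relabeling. A single-task permutation variant is kept for distributional
checks (a single task's null accuracy is Binomial(n_test, 0.5)/n_test on
no-signal data).

A related caveat, observed on synthetic data and relevant to real
generalization designs: a *strong* training-set signal that does not
transfer to the test condition (e.g. a word-form component under
across-language testing) gives the observed accuracy a fixed per-subject
random-projection bias that permuted training labels cannot reproduce, so
permutation p-values in non-transfer windows become anti-conservative.
The ground-truth recovery tests therefore embed the concept component
alone when validating across-language timing.

Group inference counts individually significant subjects (p < 0.05) per
window and compares the count against Binomial(n_subjects, 0.05) (exact
upper tail), then corrects over windows with Benjamini–Hochberg FDR at 5%.

## Frequency-band importance

Thirty band-stop versions of the epoched signal are produced (4 Hz wide
bands centered 2, 4, …, 60 Hz) and the decoding analysis is repeated on
each. Importance of band b at window w is the odds ratio
`OR = [a/(1−a)] / [a_b/(1−a_b)]` of the unfiltered accuracy `a` against
the band-removed accuracy `a_b`; accuracies are clamped to
`[ε, 1−ε]`, `ε = 1/(2·n_test)` (half a count), so the ratio stays finite.
OR > 1 means the band carried information. Group statistics: two-sided
Wilcoxon signed-rank of the per-subject ORs against 1, FDR-corrected
jointly over all band × window cells.

Band removal is DFT-domain excision over the full 2 s epoch (rfft bins in
[center − 2, center + 2] Hz zeroed, inverse transform): exactly zero-phase
with complete in-band attenuation at 0.5 Hz bin resolution. An FIR
band-stop with a usefully narrow transition band would need more taps than
the epoch has samples and cannot be applied forward–backward to these
data. Note that a transient component's spectral width is set by its
envelope: a 150 ms Hann-enveloped 6 Hz burst spreads well beyond one 4 Hz
band, so band-level attribution is only crisp for sustained (≥ ~400 ms)
carriers — the band-importance validation uses a 400 ms concept support
for this reason.

## Phoneme distances

The stimulus dissimilarity measure is the Levenshtein distance between
broad phonemic transcriptions (insertions, deletions, substitutions, by
dynamic programming) divided by the phoneme count of the longer word. The
packaged transcriptions use non-rhotic British-style English (no coda /r/
in "horse"/"shark") and broad standard Dutch; under this convention every
English–Dutch pair is maximally distant (mean 1.00, SD 0.00 over all 16
cross-language pairs). Within-language means (0.92 Dutch, 0.94 English
with this fixture) depend on the transcription convention and are
reported descriptively. Transcriptions are data, not computed; no
grapheme-to-phoneme conversion is attempted.

## Statistical primitives

Benjamini–Hochberg FDR goes through statsmodels; the exact binomial tail
through scipy. Both are additionally checked in the test suite against
brute-force oracles (rank-threshold scan; direct enumeration of the
binomial sum), as is the Levenshtein DP against a recursive oracle.

## Problem sizes used in validation

Simulation-based tests run at reduced size, chosen as the smallest
configurations at which the tested effects are identifiable: cohorts of 8
subjects (12 for the band-importance study, because the exact signed-rank
test with n = 8 has a two-sided p floor of 0.0078, too coarse to survive
FDR over 300 cells; n = 12 gives ~4.9 × 10⁻⁴), 16 trials per noun per
language (4 runs × 4 repetitions), 12 channels, 40 ms windows every 100 ms
across the post-onset second, and 100 permutations. Recovery criteria are
evaluated over 20 independently seeded cohorts per condition. The
acceptance script runs the chance-level check at the full design (62
channels, 48 trials/noun/language, 200 permutations).

## Known limitations

* Topographies and noise covariance are random, not anatomical; channel
  count is a pure dimensionality parameter.
* Component latencies are fixed within subject; real semantic latencies
  jitter across trials, which lowers attainable accuracy and blurs window
  boundaries.
* The epoched generator draws each trial's noise independently, so
  temporal autocorrelation across trials (drifts, slow artifacts) is
  absent; the continuous generator has within-block continuity but is used
  only for exercising the preprocessing path.
* The permutation caveat above means across-condition generalization
  p-values should be interpreted cautiously whenever the training
  condition contains strong non-transferable structure.
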