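# worddecode

Single-trial EEG decoding of spoken words in bilingual listeners:
speaker-invariant **within-language** word discrimination and
**across-language** semantic generalization, with the full statistical
machinery (permutation nulls, binomial group inference, FDR), univariate
ERP/ERSP analyses, leave-band-out frequency importance, phoneme-distance
utilities — and a synthetic-data generator that emulates the bilingual
listening experiment so the whole pipeline is verifiable against known
ground truth without any data download.

## Who this is for

Researchers doing multivariate pattern analysis (MVPA) of M/EEG speech and
language data, and anyone who needs a tested reference implementation of
sliding-window decoding with cross-condition generalization and
permutation-based group statistics.

## The analysis

Dutch–English bilinguals listen to four animal nouns in both languages
("paard"/"horse", …), each spoken by three speakers; 62-channel EEG at
250 Hz is epoched −1000..1000 ms around word onset. All classifications
are binary linear-SVM decisions (chance 0.5) on features from a 40 ms
sliding window × all channels, z-scored by training statistics:

* **within-language**: discriminate two word forms of one language, train
  on two speakers (32 trials/word), test on the held-out speaker
  (16 trials/word) — success implies speaker-invariant word information;
* **across-language**: discriminate two *concepts*, train on one
  language's word forms (48 trials/word), test on the translation
  equivalents of the other language — success implies language-invariant
  semantic-conceptual information.

Accuracies are averaged over all word/concept pairs, folds and
directions. Per subject, a 200-fold label-permutation null gives
`p = (1 + #{null ≥ obs}) / 201` per window; the group test counts
individually significant subjects against Binomial(n, 0.05) and corrects
over windows with Benjamini–Hochberg FDR (α = 5%). Frequency-band
importance removes one 4 Hz band at a time (30 bands, 2–60 Hz) and
expresses the accuracy change as an odds ratio
`[a/(1−a)] / [a_b/(1−a_b)]` (> 1: the band carried information). See
`docs/methods.md` for the model details and design choices.

## Worked example

Simulate a small cohort with a language-invariant concept component
embedded at 500–650 ms and ask whether across-language decoding recovers
it:

```python
from worddecode import ExperimentDesign, GeneratorConfig, simulate_cohort
from worddecode.mvpa import WindowSpec, decode_cohort

design = ExperimentDesign.scaled(16, n_channels=12)   # 16 trials/noun/language
cfg = GeneratorConfig(seed=7, amp_wordform=0.0, amp_speaker=0.0, amp_concept=5.0)
cohort = simulate_cohort(8, design, cfg)

windows = WindowSpec(step_samples=25, range_ms=(0.0, 1000.0))  # 40 ms windows every 100 ms
tc = decode_cohort(cohort, "across", windows, n_perm=100, seed=7)
print(tc.to_frame().to_string(index=False))
```

```
 window_center_ms  accuracy  n_sig_subjects      group_p  sig_raw  sig_fdr
             20.0  0.485026               0 1.000000e+00    False    False
            120.0  0.511719               2 5.724465e-02    False    False
            220.0  0.508464               2 5.724465e-02    False    False
            320.0  0.494792               0 1.000000e+00    False    False
            420.0  0.517253               2 5.724465e-02    False    False
            520.0  0.744792               7 5.976563e-09     True     True
            620.0  0.882812               8 3.906250e-11     True     True
            720.0  0.490560               1 3.365796e-01    False    False
            820.0  0.500977               2 5.724465e-02    False    False
            920.0  0.516927               2 5.724465e-02    False    False
```

Only the two windows overlapping the embedded 500–650 ms concept
component are group-significant (7 and 8 of 8 subjects individually
significant); everywhere else accuracy stays at chance — the decoder
recovers both the existence and the timing of the language-invariant
signal.

The stimulus phoneme distances (normalized Levenshtein, edit count divided
by the longer word's phoneme length):

```python
from worddecode.pipeline import phonetics_report
dists, summary = phonetics_report()
print(summary.to_string(index=False))
```

```
  group     mean       sd  n
  cross 1.000000 0.000000 16
  dutch 0.916667 0.129099  6
english 0.944444 0.136083  6
```

Every English–Dutch pair is maximally distant (1.00 ± 0.00): across-language
generalization cannot ride on phonological overlap.

There is also a CLI (`worddecode simulate | preprocess | erp | ersp |
decode | band-importance | phonetics | run-all`), each subcommand a thin
wrapper over the library with uniform `--seed/--out/--config` flags;
`run-all` executes the whole pipeline from one YAML config and writes
TSV/JSON results plus a SHA-256 manifest that is byte-identical across
reruns of the same config.

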