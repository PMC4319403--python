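"""Sliding-window multivariate decoding with permutation and group inference.

Two complementary cross-validation schemes probe different invariances:

* *within-language* word discrimination: binary classifiers separate the
  word forms of one language, trained on trials from two of the three
  speakers and tested on the held-out speaker (3 folds).  With the full
  design this gives 32 training and 16 test trials per word.  Accuracy is
  averaged over the 6 word pairs x 2 languages x 3 folds.
* *across-language* semantic generalization: classifiers separate two
  concepts using the word forms of one language (48 trials per word in the
  full design) and are tested on the translation-equivalent word forms of
  the other language; both directions are evaluated for each of the 6
  concept pairs (12 directed tasks).  Above-chance transfer requires
  language-invariant information.

All classifications are binary (chance 0.5).  Features are all channels x
the samples of a 40 ms sliding window, flattened and z-scored with
training-set statistics.  Per-subject significance comes from a label-
permutation null (training labels only, cross-validation structure kept);
group significance counts individually significant subjects against
Binomial(n_subjects, 0.05) and corrects over windows with BH-FDR.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .containers import EpochedDataset
from .stats import bh_fdr, group_binomial, permutation_p
from .svm import _dual_cd, svm_decision, svm_fit

__all__ = [
    "WindowSpec",
    "ClassifierSpec",
    "PairwiseTask",
    "SubjectDecoding",
    "AccuracyTimecourse",
    "make_speaker_folds",
    "make_language_splits",
    "within_language_tasks",
    "across_language_tasks",
    "classify_window",
    "timecourse",
    "permutation_null",
    "permutation_null_task",
    "decode_subject",
    "group_timecourse",
    "decode_cohort",
]


@dataclass(frozen=True)
class WindowSpec:
    """Sliding temporal windows: ``width_ms`` wide (40 ms = 10 samples at
    250 Hz), advanced by ``step_samples``, restricted to ``range_ms`` if
    given (otherwise the full epoch)."""

    width_ms: float = 40.0
    step_samples: int = 1
    range_ms: tuple[float, float] | None = None

    def width_samples(self, sampling_rate: float) -> int:
        w = self.width_ms / 1000.0 * sampling_rate
        if not np.isclose(w, round(w)) or round(w) < 1:
            raise ValueError(
                f"width {self.width_ms} ms is not a whole number of samples "
                f"at {sampling_rate} Hz"
            )
        return int(round(w))

    def windows(self, epochs: EpochedDataset) -> tuple[np.ndarray, int]:
        """(array of window start samples, window length in samples)."""
        width = self.width_samples(epochs.sampling_rate)
        if self.range_ms is None:
            lo, hi = 0, epochs.n_samples
        else:
            lo = epochs.sample_at(self.range_ms[0])
            hi = epochs.sample_at(self.range_ms[1])
        starts = np.arange(lo, hi - width + 1, self.step_samples)
        if len(starts) == 0:
            raise ValueError("window range shorter than the window width")
        return starts, width

    def centers_ms(self, epochs: EpochedDataset) -> np.ndarray:
        starts, width = self.windows(epochs)
        return epochs.tmin_ms + (starts + width / 2.0) * 1000.0 / epochs.sampling_rate


@dataclass(frozen=True)
class ClassifierSpec:
    """Linear-SVM settings: soft-margin constant ``C``, pass cap
    ``max_iter`` and dual-gap stopping tolerance ``tol``."""

    C: float = 1.0
    max_iter: int = 15000
    tol: float = 0.01

    def __post_init__(self) -> None:
        if self.max_iter <= 0 or self.C <= 0:
            raise ValueError("C and max_iter must be positive")


@dataclass
class PairwiseTask:
    """One binary train/test split; ``y`` is 0 for ``class_a``, 1 for
    ``class_b``.  Ties of the decision function are resolved to class_a."""

    name: str
    class_a: str
    class_b: str
    train_idx: np.ndarray
    train_y: np.ndarray
    test_idx: np.ndarray
    test_y: np.ndarray

    def __post_init__(self) -> None:
        if np.intersect1d(self.train_idx, self.test_idx).size:
            raise ValueError(f"task {self.name}: train and test overlap")
        for part, y in (("train", self.train_y), ("test", self.test_y)):
            if len(np.unique(y)) < 2:
                raise ValueError(f"task {self.name}: {part} set misses a class")


@dataclass
class SubjectDecoding:
    """Per-subject decoding result over windows."""

    window_centers_ms: np.ndarray
    accuracy: np.ndarray
    p: np.ndarray | None = None  # permutation p per window
    n_test: int = 0              # test evaluations contributing per window


@dataclass
class AccuracyTimecourse:
    """Group-level decoding time course with per-subject detail."""

    window_centers_ms: np.ndarray
    accuracy: np.ndarray               # group mean per window
    subject_accuracy: np.ndarray       # subjects x windows
    subject_p: np.ndarray              # subjects x windows
    group_k: np.ndarray                # significant subjects per window
    group_p: np.ndarray
    group_sig_raw: np.ndarray
    group_sig_fdr: np.ndarray
    n_test: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "window_center_ms": self.window_centers_ms,
                "accuracy": self.accuracy,
                "n_sig_subjects": self.group_k,
                "group_p": self.group_p,
                "sig_raw": self.group_sig_raw,
                "sig_fdr": self.group_sig_fdr,
            }
        )


# ---------------------------------------------------------------------------
# cross-validation constructors


def make_speaker_folds(meta: pd.DataFrame,
                       n_speakers: int = 3) -> list[tuple[np.ndarray, np.ndarray]]:
    """Leave-one-speaker-out folds over all (animal) trials.

    Returns ``n_speakers`` (train_mask, test_mask) pairs; each fold trains
    on the other speakers and tests on the held-out one.  With the full
    design: 32 training and 16 test trials per word per fold.
    """
    speakers = np.sort(meta["speaker"].unique())
    if len(speakers) != n_speakers:
        raise ValueError(
            f"expected {n_speakers} speakers, found {list(speakers)}"
        )
    folds = []
    for test_speaker in speakers:
        test = (meta["speaker"] == test_speaker).to_numpy()
        folds.append((~test, test))
    return folds


def within_language_tasks(meta: pd.DataFrame, n_speakers: int = 3,
                          languages: tuple[str, str] = ("dutch", "english")
                          ) -> list[PairwiseTask]:
    """All within-language pairwise tasks: word pairs x languages x
    speaker folds (6 x 2 x 3 = 36 with the full design)."""
    folds = make_speaker_folds(meta, n_speakers)
    tasks = []
    for language in languages:
        in_lang = (meta["language"] == language).to_numpy()
        forms = list(dict.fromkeys(meta.loc[in_lang, "word_form"]))
        for wf_a, wf_b in combinations(sorted(forms), 2):
            is_a = (meta["word_form"] == wf_a).to_numpy()
            is_b = (meta["word_form"] == wf_b).to_numpy()
            in_pair = in_lang & (is_a | is_b)
            for f_i, (train_m, test_m) in enumerate(folds):
                tr = np.where(in_pair & train_m)[0]
                te = np.where(in_pair & test_m)[0]
                tasks.append(
                    PairwiseTask(
                        name=f"{language}:{wf_a}-vs-{wf_b}:fold{f_i}",
                        class_a=wf_a, class_b=wf_b,
                        train_idx=tr, train_y=is_b[tr].astype(int),
                        test_idx=te, test_y=is_b[te].astype(int),
                    )
                )
    return tasks


def make_language_splits(meta: pd.DataFrame, concept_pair: tuple[str, str],
                         languages: tuple[str, str] = ("dutch", "english")
                         ) -> list[PairwiseTask]:
    """Both directed across-language splits for one concept pair.

    Training uses the two concepts' word forms in one language, testing
    the translation equivalents in the other; labels are carried by
    concept, not word form.
    """
    c_a, c_b = concept_pair
    is_a = (meta["concept"] == c_a).to_numpy()
    is_b = (meta["concept"] == c_b).to_numpy()
    tasks = []
    for train_lang, test_lang in (languages, languages[::-1]):
        tr_lang = (meta["language"] == train_lang).to_numpy()
        te_lang = (meta["language"] == test_lang).to_numpy()
        tr = np.where((is_a | is_b) & tr_lang)[0]
        te = np.where((is_a | is_b) & te_lang)[0]
        if not len(tr) or not len(te):
            raise ValueError(
                f"concept pair {concept_pair} not present in both languages"
            )
        tasks.append(
            PairwiseTask(
                name=f"{c_a}-vs-{c_b}:{train_lang}->{test_lang}",
                class_a=c_a, class_b=c_b,
                train_idx=tr, train_y=is_b[tr].astype(int),
                test_idx=te, test_y=is_b[te].astype(int),
            )
        )
    return tasks


def across_language_tasks(meta: pd.DataFrame,
                          languages: tuple[str, str] = ("dutch", "english")
                          ) -> list[PairwiseTask]:
    """All directed across-language tasks (6 concept pairs x 2 directions)."""
    concepts = sorted(set(meta["concept"]) - {""})
    tasks = []
    for pair in combinations(concepts, 2):
        tasks.extend(make_language_splits(meta, pair, languages))
    return tasks


# ---------------------------------------------------------------------------
# classification


def _window_features(data: np.ndarray, idx: np.ndarray, start: int,
                     width: int) -> np.ndarray:
    return data[idx, :, start:start + width].reshape(len(idx), -1)


def _accuracy(Xtr: np.ndarray, ytr: np.ndarray, Xte: np.ndarray,
              yte: np.ndarray, spec: ClassifierSpec) -> float:
    mu = Xtr.mean(axis=0)
    sd = Xtr.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)  # zero-variance features left unscaled
    w = svm_fit((Xtr - mu) / sd, ytr, C=spec.C, max_iter=spec.max_iter,
                tol=spec.tol)
    score = svm_decision(w, (Xte - mu) / sd)
    pred = (score > 0).astype(int)  # ties (score == 0) -> class_a
    return float(np.mean(pred == yte))


def classify_window(epochs: EpochedDataset, task: PairwiseTask,
                    window: tuple[int, int],
                    spec: ClassifierSpec = ClassifierSpec()) -> float:
    """Accuracy of one pairwise task on one (start, width) sample window."""
    start, width = window
    if start < 0 or start + width > epochs.n_samples:
        raise ValueError("window outside the epoch")
    Xtr = _window_features(epochs.data, task.train_idx, start, width)
    Xte = _window_features(epochs.data, task.test_idx, start, width)
    return _accuracy(Xtr, task.train_y, Xte, task.test_y, spec)


def timecourse(epochs: EpochedDataset, tasks: list[PairwiseTask],
               wspec: WindowSpec = WindowSpec(),
               cspec: ClassifierSpec = ClassifierSpec()) -> SubjectDecoding:
    """Mean accuracy over tasks for every sliding window."""
    starts, width = wspec.windows(epochs)
    acc = np.zeros(len(starts))
    for task in tasks:
        for w_i, start in enumerate(starts):
            acc[w_i] += classify_window(epochs, task, (start, width), cspec)
    acc /= len(tasks)
    n_test = sum(len(t.test_idx) for t in tasks)
    return SubjectDecoding(
        window_centers_ms=wspec.centers_ms(epochs), accuracy=acc, n_test=n_test
    )


def _fast_accuracy(Xw: np.ndarray, tr_idx: np.ndarray, y_signed: np.ndarray,
                   te_idx: np.ndarray, te_y: np.ndarray,
                   cspec: ClassifierSpec) -> float:
    """Accuracy from a precomputed full-trial feature matrix ``Xw``."""
    Xtr = Xw[tr_idx]
    mu = Xtr.mean(axis=0)
    sd = Xtr.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    Xtr_s = np.empty((len(tr_idx), Xw.shape[1] + 1))
    Xtr_s[:, :-1] = (Xtr - mu) / sd
    Xtr_s[:, -1] = 1.0
    w = _dual_cd(Xtr_s, y_signed, cspec.C, cspec.max_iter, cspec.tol)
    score = ((Xw[te_idx] - mu) / sd) @ w[:-1] + w[-1]
    return float(np.mean((score > 0).astype(int) == te_y))


def permutation_null_task(epochs: EpochedDataset, task: PairwiseTask,
                          wspec: WindowSpec, cspec: ClassifierSpec,
                          n_perm: int, rng: np.random.Generator) -> np.ndarray:
    """Single-task null accuracies (n_perm x windows): the task's training
    labels are permuted, its test labels stay fixed."""
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    starts, width = wspec.windows(epochs)
    n_trials = epochs.n_trials
    null = np.zeros((n_perm, len(starts)))
    perms = [np.where(rng.permutation(task.train_y) > 0, 1.0, -1.0)
             for _ in range(n_perm)]
    for w_i, start in enumerate(starts):
        Xw = epochs.data[:, :, start:start + width].reshape(n_trials, -1)
        for p_i, y_signed in enumerate(perms):
            null[p_i, w_i] = _fast_accuracy(Xw, task.train_idx, y_signed,
                                            task.test_idx, task.test_y, cspec)
    return null


def _across_permuter(meta: pd.DataFrame,
                     languages: tuple[str, str] = ("dutch", "english")):
    """Coherent label permuter for across-language tasks.

    One permutation iteration shuffles the concept labels of each
    language's trials once; every directed task is rebuilt from the same
    permuted labeling (training side only; test labels stay true), so the
    correlation between the overlapping pairwise tasks is preserved."""
    concepts = sorted(set(meta["concept"]) - {""})
    lang_idx = {
        lang: np.where((meta["language"] == lang).to_numpy())[0]
        for lang in languages
    }
    lang_conc = {lang: meta["concept"].to_numpy()[lang_idx[lang]]
                 for lang in languages}
    fixed_tests = {}
    for c_a, c_b in combinations(concepts, 2):
        for test_lang in languages:
            is_pair = np.isin(lang_conc[test_lang], (c_a, c_b))
            te_idx = lang_idx[test_lang][is_pair]
            te_y = (lang_conc[test_lang][is_pair] == c_b).astype(int)
            fixed_tests[(c_a, c_b, test_lang)] = (te_idx, te_y)

    def draw(rng: np.random.Generator):
        permuted = {lang: rng.permutation(lang_conc[lang]) for lang in languages}
        tasks = []
        for c_a, c_b in combinations(concepts, 2):
            for train_lang, test_lang in (languages, languages[::-1]):
                labels = permuted[train_lang]
                sel = np.isin(labels, (c_a, c_b))
                tr_idx = lang_idx[train_lang][sel]
                y_signed = np.where(labels[sel] == c_b, 1.0, -1.0)
                te_idx, te_y = fixed_tests[(c_a, c_b, test_lang)]
                tasks.append((tr_idx, y_signed, te_idx, te_y))
        return tasks

    return draw


def _within_permuter(meta: pd.DataFrame, n_speakers: int = 3,
                     languages: tuple[str, str] = ("dutch", "english")):
    """Coherent label permuter for within-language tasks.

    Word-form labels are shuffled within each language x speaker stratum
    (so every speaker fold keeps its class balance); all word-pair x fold
    tasks are rebuilt from the same permuted labeling, test sides fixed."""
    folds = make_speaker_folds(meta, n_speakers)
    language = meta["language"].to_numpy()
    speaker = meta["speaker"].to_numpy()
    word = meta["word_form"].to_numpy()
    strata = [np.where((language == lang) & (speaker == spk))[0]
              for lang in languages for spk in np.unique(speaker)]
    pairs = []
    for lang in languages:
        forms = sorted(set(word[language == lang]))
        for wf_a, wf_b in combinations(forms, 2):
            for f_i, (train_m, test_m) in enumerate(folds):
                in_pair = np.isin(word, (wf_a, wf_b)) & (language == lang)
                te_idx = np.where(in_pair & test_m)[0]
                te_y = (word[te_idx] == wf_b).astype(int)
                tr_mask = in_pair & train_m
                pairs.append((lang, wf_a, wf_b, tr_mask, te_idx, te_y, train_m))

    def draw(rng: np.random.Generator):
        permuted = word.copy()
        for idx in strata:
            permuted[idx] = rng.permutation(permuted[idx])
        tasks = []
        for lang, wf_a, wf_b, _, te_idx, te_y, train_m in pairs:
            sel = np.isin(permuted, (wf_a, wf_b)) & (language == lang) & train_m
            tr_idx = np.where(sel)[0]
            y_signed = np.where(permuted[tr_idx] == wf_b, 1.0, -1.0)
            tasks.append((tr_idx, y_signed, te_idx, te_y))
        return tasks

    return draw


def permutation_null(epochs: EpochedDataset, mode: str,
                     wspec: WindowSpec, cspec: ClassifierSpec,
                     n_perm: int, rng: np.random.Generator,
                     n_speakers: int = 3) -> np.ndarray:
    """Null accuracies (n_perm x windows) for the full task set of a mode.

    Each permutation iteration shuffles trial labels once within every
    cross-validation stratum and reruns the complete pairwise analysis on
    the relabeled training data (test labels fixed), then averages over
    tasks — exactly the pipeline applied to the observed labels.  A single
    coherent relabeling per iteration preserves the correlation between
    the overlapping pairwise tasks; permuting each task independently
    would shrink the variance of the task-averaged null and make the
    p-values anti-conservative.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if mode == "across":
        draw = _across_permuter(epochs.meta)
    elif mode == "within":
        draw = _within_permuter(epochs.meta, n_speakers)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    starts, width = wspec.windows(epochs)
    n_trials = epochs.n_trials
    windows = [
        np.ascontiguousarray(
            epochs.data[:, :, start:start + width].reshape(n_trials, -1)
        )
        for start in starts
    ]
    null = np.zeros((n_perm, len(starts)))
    for p_i in range(n_perm):
        tasks = draw(rng)
        for w_i, Xw in enumerate(windows):
            acc = 0.0
            for tr_idx, y_signed, te_idx, te_y in tasks:
                acc += _fast_accuracy(Xw, tr_idx, y_signed, te_idx, te_y, cspec)
            null[p_i, w_i] = acc / len(tasks)
    return null


def decode_subject(epochs: EpochedDataset, mode: str,
                   wspec: WindowSpec = WindowSpec(),
                   cspec: ClassifierSpec = ClassifierSpec(),
                   n_perm: int = 200,
                   rng: np.random.Generator | None = None,
                   n_speakers: int = 3) -> SubjectDecoding:
    """Full single-subject decoding time course with permutation p-values.

    ``mode`` is ``"within"`` (speaker-invariant word discrimination) or
    ``"across"`` (cross-language concept generalization).
    """
    if mode == "within":
        tasks = within_language_tasks(epochs.meta, n_speakers=n_speakers)
    elif mode == "across":
        tasks = across_language_tasks(epochs.meta)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    result = timecourse(epochs, tasks, wspec, cspec)
    if n_perm:
        if rng is None:
            rng = np.random.default_rng()
        null = permutation_null(epochs, mode, wspec, cspec, n_perm, rng,
                                n_speakers=n_speakers)
        result.p = permutation_p(result.accuracy, null)
    return result


def group_timecourse(results: list[SubjectDecoding], alpha_subject: float = 0.05,
                     p0: float = 0.05, alpha: float = 0.05) -> AccuracyTimecourse:
    """Combine per-subject decodings into the group-level time course."""
    if not results:
        raise ValueError("no subject results")
    centers = results[0].window_centers_ms
    for r in results[1:]:
        if not np.array_equal(r.window_centers_ms, centers):
            raise ValueError("subjects decoded on different window grids")
    acc = np.stack([r.accuracy for r in results])
    pvals = np.stack([r.p for r in results])
    sig = pvals < alpha_subject
    group = group_binomial(sig, p0=p0, alpha=alpha)
    return AccuracyTimecourse(
        window_centers_ms=centers,
        accuracy=acc.mean(axis=0),
        subject_accuracy=acc,
        subject_p=pvals,
        group_k=group["k"],
        group_p=group["p"],
        group_sig_raw=group["sig_raw"],
        group_sig_fdr=group["sig_fdr"],
        n_test=results[0].n_test,
    )


def decode_cohort(cohort: list[EpochedDataset], mode: str,
                  wspec: WindowSpec = WindowSpec(),
                  cspec: ClassifierSpec = ClassifierSpec(),
                  n_perm: int = 200, seed: int = 0,
                  alpha_subject: float = 0.05, p0: float = 0.05,
                  alpha: float = 0.05, n_speakers: int = 3) -> AccuracyTimecourse:
    """Decode every subject and run the group analysis."""
    seeds = np.random.SeedSequence([seed, 0xDEC0DE]).spawn(len(cohort))
    results = [
        decode_subject(ep, mode, wspec, cspec, n_perm,
                       np.random.default_rng(s), n_speakers=n_speakers)
        for ep, s in zip(cohort, seeds)
    ]
    return group_timecourse(results, alpha_subject=alpha_subject, p0=p0,
                            alpha=alpha)
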