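"""Cross-validation bookkeeping, classification contracts, decoding
ground-truth recovery, permutation and group inference."""

import numpy as np
import pandas as pd
import pytest

from worddecode import GeneratorConfig, simulate_cohort, simulate_subject
from worddecode.mvpa import (
    ClassifierSpec,
    PairwiseTask,
    WindowSpec,
    across_language_tasks,
    classify_window,
    decode_cohort,
    decode_subject,
    group_timecourse,
    make_language_splits,
    make_speaker_folds,
    permutation_null,
    timecourse,
    within_language_tasks,
)

from conftest import toy_epochs

WS5 = WindowSpec(step_samples=50, range_ms=(0.0, 1000.0))  # 5 windows


class TestSpeakerFolds:
    def test_full_design_train32_test16_per_word(self, default_schedule):
        meta = default_schedule.animal_trials
        folds = make_speaker_folds(meta)
        assert len(folds) == 3
        for train_m, test_m in folds:
            per_word_train = meta[train_m].groupby(["language", "word_form"]).size()
            per_word_test = meta[test_m].groupby(["language", "word_form"]).size()
            assert (per_word_train == 32).all()
            assert (per_word_test == 16).all()

    def test_test_sets_partition_all_trials(self, default_schedule):
        meta = default_schedule.animal_trials
        folds = make_speaker_folds(meta)
        stacked = np.stack([test for _, test in folds])
        assert (stacked.sum(axis=0) == 1).all()  # disjoint and exhaustive

    def test_rejected_trial_shrinks_only_its_fold(self, default_schedule):
        meta = default_schedule.animal_trials
        drop = meta.index[
            (meta["word_form"] == "paard") & (meta["speaker"] == 1)
        ][0]
        reduced = meta.drop(index=drop).reset_index(drop=True)
        folds = make_speaker_folds(reduced)
        counts = sorted(
            reduced[test].query("word_form == 'paard'").shape[0]
            for _, test in folds
        )
        assert counts == [15, 16, 16]

    def test_missing_speaker_rejected(self, default_schedule):
        meta = default_schedule.animal_trials
        partial = meta[meta["speaker"] != 2].reset_index(drop=True)
        with pytest.raises(ValueError, match="speakers"):
            make_speaker_folds(partial)


class TestLanguageSplits:
    def test_full_design_48_train_48_test(self, default_schedule):
        meta = default_schedule.animal_trials
        for task in make_language_splits(meta, ("bull", "duck")):
            assert len(task.train_idx) == 96   # 48 per word
            assert len(task.test_idx) == 96
            assert not np.intersect1d(task.train_idx, task.test_idx).size

    def test_twelve_directed_tasks(self, default_schedule):
        tasks = across_language_tasks(default_schedule.animal_trials)
        assert len(tasks) == 12  # C(4,2)=6 pairs x 2 directions
        names = {t.name for t in tasks}
        assert "bull-vs-duck:dutch->english" in names
        assert "bull-vs-duck:english->dutch" in names

    def test_labels_carried_by_concept_not_word_form(self, default_schedule):
        meta = default_schedule.animal_trials
        task = make_language_splits(meta, ("horse", "shark"))[0]
        train_words = set(meta.iloc[task.train_idx]["word_form"])
        test_words = set(meta.iloc[task.test_idx]["word_form"])
        assert train_words == {"paard", "haai"}
        assert test_words == {"horse", "shark"}

    def test_missing_concept_rejected(self, default_schedule):
        meta = default_schedule.animal_trials
        with pytest.raises(ValueError):
            make_language_splits(meta, ("bull", "wolf"))


def _toy_task(n_train=8, n_test=8):
    y_tr = np.repeat([0, 1], n_train // 2)
    y_te = np.repeat([0, 1], n_test // 2)
    return PairwiseTask(
        name="toy", class_a="a", class_b="b",
        train_idx=np.arange(n_train), train_y=y_tr,
        test_idx=n_train + np.arange(n_test), test_y=y_te,
    )


class TestClassifyWindow:
    def _epochs_from_patterns(self, pat_a, pat_b, n_each=4, noise=0.0, seed=0):
        rng = np.random.default_rng(seed)
        trials = []
        for y in np.repeat([0, 1], n_each):           # train block
            trials.append([pat_a, pat_b][y] + noise * rng.normal(size=pat_a.shape))
        for y in np.repeat([0, 1], n_each):           # test block
            trials.append([pat_a, pat_b][y] + noise * rng.normal(size=pat_a.shape))
        return toy_epochs(np.stack(trials))

    def test_separable_patterns_give_perfect_accuracy(self):
        rng = np.random.default_rng(1)
        pat_a, pat_b = rng.normal(size=(2, 3, 500))
        epochs = self._epochs_from_patterns(pat_a, pat_b, noise=0.05)
        acc = classify_window(epochs, _toy_task(), (100, 10))
        assert acc == 1.0

    def test_no_information_resolves_to_class_a(self):
        pat = np.zeros((3, 500))
        epochs = self._epochs_from_patterns(pat, pat, noise=0.0)
        # identical constant patterns: decision is a tie, resolved to
        # class_a, so accuracy equals the class_a share of the test set
        acc = classify_window(epochs, _toy_task(), (100, 10))
        assert acc == 0.5

    def test_channel_permutation_invariance(self, small_epochs):
        tasks = across_language_tasks(small_epochs.meta)
        perm = np.random.default_rng(2).permutation(small_epochs.n_channels)
        permuted = small_epochs.copy_with(small_epochs.data[:, perm, :])
        for task in tasks[:3]:
            a = classify_window(small_epochs, task, (250, 10))
            b = classify_window(permuted, task, (250, 10))
            assert a == b

    def test_constant_feature_shift_invariance(self, small_epochs):
        task = across_language_tasks(small_epochs.meta)[0]
        shifted = small_epochs.copy_with(small_epochs.data + 7.5)
        a = classify_window(small_epochs, task, (300, 10))
        b = classify_window(shifted, task, (300, 10))
        assert a == pytest.approx(b, abs=1e-12)

    def test_window_outside_epoch_rejected(self, small_epochs):
        task = across_language_tasks(small_epochs.meta)[0]
        with pytest.raises(ValueError, match="outside"):
            classify_window(small_epochs, task, (495, 10))


def test_single_window_timecourse_reduces_to_one_classification(small_epochs):
    tasks = across_language_tasks(small_epochs.meta)[:2]
    ws = WindowSpec(width_ms=2000.0, step_samples=500)
    tc = timecourse(small_epochs, tasks, ws)
    assert len(tc.accuracy) == 1
    direct = np.mean([classify_window(small_epochs, t, (0, 500)) for t in tasks])
    assert tc.accuracy[0] == pytest.approx(direct)


def test_direction_average_is_mean_of_directed_accuracies(small_epochs):
    pair_tasks = make_language_splits(small_epochs.meta, ("bull", "horse"))
    ws = WindowSpec(step_samples=250, range_ms=(0.0, 1000.0))
    tc = timecourse(small_epochs, pair_tasks, ws)
    directed = [timecourse(small_epochs, [t], ws).accuracy for t in pair_tasks]
    np.testing.assert_allclose(tc.accuracy, np.mean(directed, axis=0))


class TestGroundTruthRecovery:
    def test_wordform_signal_survives_speaker_crossvalidation(self, small_design):
        """Strong word-form + speaker signal: decodable in the word-form
        window (the word pattern is shared across speakers), at chance
        late in the epoch."""
        cfg = GeneratorConfig(seed=31, amp_wordform=5.0, amp_speaker=5.0,
                              amp_concept=0.0,
                              wordform_window_ms=(50.0, 400.0))
        cohort = simulate_cohort(3, small_design, cfg)
        accs = np.mean(
            [decode_subject(ep, "within", WS5, n_perm=0).accuracy
             for ep in cohort], axis=0)
        centers = WS5.centers_ms(cohort[0])
        in_window = (centers > 50) & (centers < 400)
        assert accs[in_window].max() > 0.7
        assert abs(accs[centers > 700].mean() - 0.5) < 0.08

    def test_speaker_only_signal_is_chance(self, small_design):
        """Speaker cross-validation removes the speaker shortcut."""
        cfg = GeneratorConfig(seed=32, amp_wordform=0.0, amp_speaker=8.0,
                              amp_concept=0.0)
        cohort = simulate_cohort(4, small_design, cfg)
        accs = np.mean(
            [decode_subject(ep, "within", WS5, n_perm=0).accuracy
             for ep in cohort], axis=0)
        assert np.abs(accs - 0.5).max() < 0.1
        assert abs(accs.mean() - 0.5) < 0.05

    def test_wordform_signal_does_not_transfer_across_languages(self, small_design):
        """Word-form patterns are word-specific, so across-language
        generalization stays at chance without a concept component."""
        cfg = GeneratorConfig(seed=33, amp_wordform=6.0, amp_speaker=0.0,
                              amp_concept=0.0)
        cohort = simulate_cohort(4, small_design, cfg)
        accs = np.mean(
            [decode_subject(ep, "across", WS5, n_perm=0).accuracy
             for ep in cohort], axis=0)
        assert np.abs(accs - 0.5).max() < 0.12
        assert abs(accs.mean() - 0.5) < 0.05

    def test_concept_signal_transfers_only_in_its_window(self, small_design):
        cfg = GeneratorConfig(seed=34, amp_wordform=0.0, amp_speaker=0.0,
                              amp_concept=6.0)
        ep = simulate_cohort(1, small_design, cfg)[0]
        r = decode_subject(ep, "across", WS5, n_perm=0)
        centers = r.window_centers_ms
        overlap = (centers > 460) & (centers < 690)
        assert r.accuracy[overlap].max() > 0.65
        assert np.abs(r.accuracy[~overlap] - 0.5).max() < 0.15


class TestPermutationInference:
    def test_observed_above_all_nulls_gives_add_one_p(self, small_design):
        cfg = GeneratorConfig(seed=35, amp_concept=8.0, amp_wordform=0.0,
                              amp_speaker=0.0)
        ep = simulate_cohort(1, small_design, cfg)[0]
        ws = WindowSpec(step_samples=500, range_ms=(500.0, 660.0))  # one window
        r = decode_subject(ep, "across", ws, n_perm=50,
                           rng=np.random.default_rng(0))
        assert r.p[0] == pytest.approx(1 / 51)

    def test_null_respects_task_structure_and_shape(self, nosignal_epochs):
        ws = WindowSpec(step_samples=200, range_ms=(0.0, 1000.0))
        null = permutation_null(nosignal_epochs, "across", ws, ClassifierSpec(),
                                n_perm=30, rng=np.random.default_rng(1))
        assert null.shape == (30, 2)
        assert 0.35 < null.mean() < 0.65

    def test_group_pipeline_flags_expected_windows(self, small_design):
        cfg = GeneratorConfig(seed=36, amp_concept=8.0, amp_wordform=0.0,
                              amp_speaker=0.0)
        cohort = simulate_cohort(8, small_design, cfg)
        tc = decode_cohort(cohort, "across", WS5, n_perm=40, seed=9)
        centers = tc.window_centers_ms
        overlap = (centers > 460) & (centers < 690)
        assert tc.group_sig_fdr[overlap].any()
        assert not tc.group_sig_fdr[centers < 400].any()

    def test_group_requires_common_window_grid(self, small_epochs):
        a = decode_subject(small_epochs, "across", WS5, n_perm=1,
                           rng=np.random.default_rng(0))
        b = decode_subject(small_epochs, "across",
                           WindowSpec(step_samples=250, range_ms=(0.0, 1000.0)),
                           n_perm=1, rng=np.random.default_rng(0))
        with pytest.raises(ValueError, match="window grids"):
            group_timecourse([a, b])


def test_overlapping_train_test_rejected():
    with pytest.raises(ValueError, match="overlap"):
        PairwiseTask(name="bad", class_a="a", class_b="b",
                     train_idx=np.array([0, 1, 2, 3]),
                     train_y=np.array([0, 0, 1, 1]),
                     test_idx=np.array([3, 4, 5, 6]),
                     test_y=np.array([0, 0, 1, 1]))


def test_window_width_must_be_integral_samples(small_epochs):
    with pytest.raises(ValueError, match="whole number"):
        WindowSpec(width_ms=41.0).windows(small_epochs)
    starts, width = WindowSpec(width_ms=40.0).windows(small_epochs)
    assert width == 10
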