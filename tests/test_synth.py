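"""Generator ground truth: component structure, determinism, noise."""

import numpy as np
import pytest

from worddecode import (
    GeneratorConfig,
    build_schedule,
    component_epoch,
    draw_subject_patterns,
    simulate_cohort,
    simulate_subject,
)
from worddecode.preprocess import extract_epochs
from worddecode.synth import _epoch_times_ms


def test_cohorts_bit_identical_given_seed(small_design):
    cfg = GeneratorConfig(seed=21)
    a = simulate_cohort(2, small_design, cfg)
    b = simulate_cohort(2, small_design, cfg)
    for x, y in zip(a, b):
        assert np.array_equal(x.data, y.data)
        assert x.meta.equals(y.meta)


def test_subjects_share_schedule_but_differ_in_data(small_design):
    cohort = simulate_cohort(3, small_design, GeneratorConfig(seed=2))
    assert cohort[0].meta.equals(cohort[1].meta)
    assert not np.array_equal(cohort[0].data, cohort[1].data)


def test_single_subject_cohort_matches_direct_simulation(small_design):
    cfg = GeneratorConfig(seed=5)
    cohort = simulate_cohort(1, small_design, cfg)
    # the cohort's schedule seed stream is part of the contract
    direct = simulate_cohort(1, small_design, cfg)[0]
    assert np.array_equal(cohort[0].data, direct.data)


def test_zero_amplitude_grand_average_is_noise_level(small_schedule):
    cfg = GeneratorConfig(seed=3, amp_wordform=0.0, amp_speaker=0.0,
                          amp_concept=0.0)
    ep = simulate_subject(small_schedule, cfg)
    mean = ep.data.mean(axis=0)
    sem = ep.data.std(axis=0, ddof=1) / np.sqrt(ep.n_trials)
    frac = np.mean(np.abs(mean) < 3 * sem)
    assert frac > 0.985  # pure zero-mean noise: ~3-sigma bound per point


class TestComponentStructure:
    def test_concept_component_zero_outside_window(self, small_design):
        cfg = GeneratorConfig(seed=9, amp_wordform=0.0, amp_speaker=0.0,
                              amp_concept=1.0)
        patterns = draw_subject_patterns(small_design, cfg, subject=0)
        comp = component_epoch(patterns, cfg, "bull", "bull", 0)
        times = _epoch_times_ms(small_design)
        lo, hi = cfg.concept_window_ms
        outside = (times < lo) | (times >= hi)
        assert np.all(comp[:, outside] == 0.0)
        assert np.any(comp[:, ~outside] != 0.0)

    def test_wordform_pattern_shared_across_speakers(self, small_design):
        cfg = GeneratorConfig(seed=9, amp_speaker=0.0, amp_concept=0.0)
        patterns = draw_subject_patterns(small_design, cfg, subject=0)
        a = component_epoch(patterns, cfg, "paard", "horse", 0)
        b = component_epoch(patterns, cfg, "paard", "horse", 2)
        assert np.array_equal(a, b)

    def test_concept_pattern_shared_across_languages(self, small_design):
        cfg = GeneratorConfig(seed=9, amp_wordform=0.0, amp_speaker=0.0)
        patterns = draw_subject_patterns(small_design, cfg, subject=0)
        dutch = component_epoch(patterns, cfg, "paard", "horse", 1)
        english = component_epoch(patterns, cfg, "horse", "horse", 1)
        assert np.array_equal(dutch, english)

    def test_wordform_patterns_differ_between_words(self, small_design):
        cfg = GeneratorConfig(seed=9, amp_speaker=0.0, amp_concept=0.0)
        patterns = draw_subject_patterns(small_design, cfg, subject=0)
        a = component_epoch(patterns, cfg, "paard", "horse", 0)
        b = component_epoch(patterns, cfg, "horse", "horse", 0)
        assert not np.array_equal(a, b)


def test_component_window_outside_epoch_rejected(small_schedule):
    cfg = GeneratorConfig(concept_window_ms=(900.0, 1100.0))
    with pytest.raises(ValueError, match="outside epoch"):
        simulate_subject(small_schedule, cfg)


def test_invalid_amplitudes_rejected():
    with pytest.raises(ValueError, match="amp_wordform"):
        GeneratorConfig(amp_wordform=-1.0)


def test_only_animal_trials_are_epoched(small_schedule):
    ep = simulate_subject(small_schedule, GeneratorConfig(seed=1))
    assert not ep.meta["is_target"].any()
    assert ep.n_trials == len(small_schedule.animal_trials)


def test_continuous_simulation_epochs_consistently(small_schedule):
    """The continuous route carries every event and yields proper epochs."""
    from worddecode import simulate_subject_continuous

    cfg = GeneratorConfig(seed=17, amp_wordform=4.0, amp_speaker=4.0,
                          amp_concept=4.0)
    rec = simulate_subject_continuous(small_schedule, cfg)
    assert len(rec.events) == len(small_schedule.trials)
    animal = rec.events[~rec.events["is_target"]]
    epochs = extract_epochs(rec, events=animal)
    assert epochs.n_samples == 500
    assert epochs.n_trials == len(animal)
    # the embedded component is recoverable: correlate the trial-mean with
    # the noiseless component average over the same trials
    patterns = draw_subject_patterns(small_schedule.design, cfg, subject=0)
    comps = np.mean(
        [component_epoch(patterns, cfg, r.word_form, r.concept, r.speaker)
         for r in epochs.meta.itertuples(index=False)], axis=0)
    observed = epochs.data.mean(axis=0)
    corr = np.corrcoef(observed.ravel(), comps.ravel())[0, 1]
    assert corr > 0.3
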