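"""Experimental design and trial-schedule construction.

The emulated session: a bilingual listening experiment in which native Dutch
(L1) listeners, proficient in English (L2), hear four monosyllabic animal
nouns in both languages, each pronounced by three female speakers, plus
non-animal target nouns requiring a button press.  The session is organized
in runs of two blocks (one per language); within a block the presentation
order is pseudo-randomized so that the same word form never occurs twice in
a row.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ExperimentDesign",
    "TrialSchedule",
    "ScheduleError",
    "build_schedule",
]

#: concept -> (Dutch word form, English word form)
DEFAULT_WORDS: dict[str, tuple[str, str]] = {
    "bull": ("stier", "bull"),
    "duck": ("eend", "duck"),
    "horse": ("paard", "horse"),
    "shark": ("haai", "shark"),
}

DEFAULT_NONANIMAL: dict[str, tuple[str, ...]] = {
    "dutch": ("fiets", "jas", "jurk", "weg", "pak", "stad"),
    "english": ("bike", "coat", "dress", "road", "suit", "town"),
}

LANGUAGES = ("dutch", "english")  # (L1, L2)


class ScheduleError(ValueError):
    """Raised when a design cannot produce a valid pseudo-random schedule."""


@dataclass(frozen=True)
class ExperimentDesign:
    """Session layout and recording geometry.

    The defaults reproduce the full session: 8 runs x 2 blocks (one Dutch,
    one English), 24 animal + 12 non-animal trials per block, 3 speakers,
    so each animal noun occurs 6x per block and 48x per language over the
    session, and each physical stimulus (word x speaker) exactly twice per
    block.  Reduced designs (fewer runs / repetitions) are permitted for
    simulation studies as long as the counts stay internally consistent.
    """

    n_runs: int = 8
    blocks_per_run: int = 2
    words: dict[str, tuple[str, str]] = field(default_factory=lambda: dict(DEFAULT_WORDS))
    nonanimal_words: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(DEFAULT_NONANIMAL)
    )
    n_speakers: int = 3
    animal_trials_per_block: int = 24
    nonanimal_trials_per_block: int = 12
    iti_range_s: tuple[float, float] = (3.7, 4.3)
    stimulus_duration_s: float = 0.6
    epoch_window_ms: tuple[float, float] = (-1000.0, 1000.0)
    sampling_rate: float = 250.0
    n_channels: int = 62

    def __post_init__(self) -> None:
        if self.n_runs < 1 or self.blocks_per_run != len(LANGUAGES):
            raise ValueError("need >= 1 run and exactly one block per language per run")
        if self.n_speakers < 1 or self.n_channels < 1:
            raise ValueError("n_speakers and n_channels must be positive")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.animal_trials_per_block % self.n_concepts:
            raise ValueError(
                f"animal_trials_per_block={self.animal_trials_per_block} not divisible "
                f"by the {self.n_concepts} animal nouns"
            )
        for lang in LANGUAGES:
            n_na = len(self.nonanimal_words[lang])
            if self.nonanimal_trials_per_block and self.nonanimal_trials_per_block % n_na:
                raise ValueError("nonanimal_trials_per_block not divisible by word count")
        if self.iti_range_s[0] > self.iti_range_s[1] or self.iti_range_s[0] <= 0:
            raise ValueError("invalid ITI range")
        if self.epoch_window_ms[0] >= self.epoch_window_ms[1]:
            raise ValueError("invalid epoch window")

    # -- derived quantities -------------------------------------------------

    @property
    def concepts(self) -> tuple[str, ...]:
        return tuple(self.words)

    @property
    def n_concepts(self) -> int:
        return len(self.words)

    @property
    def reps_per_block(self) -> int:
        """Repetitions of each animal noun within one block (default 6)."""
        return self.animal_trials_per_block // self.n_concepts

    @property
    def trials_per_noun_per_language(self) -> int:
        """Animal trials per noun per language over the session (default 48)."""
        return self.n_runs * self.reps_per_block

    @property
    def n_blocks(self) -> int:
        return self.n_runs * self.blocks_per_run

    @property
    def trials_per_block(self) -> int:
        return self.animal_trials_per_block + self.nonanimal_trials_per_block

    def word_form(self, concept: str, language: str) -> str:
        return self.words[concept][LANGUAGES.index(language)]

    @classmethod
    def scaled(cls, trials_per_noun_per_language: int, **kwargs) -> "ExperimentDesign":
        """A reduced design with the same structure but fewer trials.

        Halves runs and per-block repetitions while keeping one block per
        language per run; non-animal trials are scaled to keep the 2:1
        animal:non-animal ratio.
        """
        n = trials_per_noun_per_language
        # factor n = n_runs * reps_per_block, preferring balanced factors
        best = None
        for n_runs in range(1, n + 1):
            if n % n_runs:
                continue
            reps = n // n_runs
            if best is None or abs(n_runs - reps) < abs(best[0] - best[1]):
                best = (n_runs, reps)
        n_runs, reps = best
        n_concepts = len(kwargs.get("words", DEFAULT_WORDS))
        animal = reps * n_concepts
        nonanimal = kwargs.pop("nonanimal_trials_per_block", 0)
        return cls(
            n_runs=n_runs,
            animal_trials_per_block=animal,
            nonanimal_trials_per_block=nonanimal,
            **kwargs,
        )


@dataclass
class TrialSchedule:
    """Ordered trial list for one session.

    ``trials`` columns: run (1-based), block (1-based within run), language,
    word_form, concept (non-animal trials: the word itself with concept
    ``""``), speaker (0-based), is_target (non-animal detection trials),
    onset_s (onset relative to block start).
    """

    trials: pd.DataFrame
    design: ExperimentDesign

    def __len__(self) -> int:
        return len(self.trials)

    @property
    def animal_trials(self) -> pd.DataFrame:
        return self.trials[~self.trials["is_target"]].reset_index(drop=True)


def _block_language(run: int, block: int) -> str:
    """Language of ``block`` (1-based) in ``run`` (1-based).

    Odd runs start with an English (L2) block followed by Dutch; even runs
    start Dutch followed by English.
    """
    first = "english" if run % 2 == 1 else "dutch"
    second = "dutch" if first == "english" else "english"
    return first if block == 1 else second


def _order_without_repeats(labels: list[str], rng: np.random.Generator,
                           max_tries: int = 200) -> np.ndarray:
    """Permutation of indices such that equal labels are never adjacent.

    Sequential sampler: the next label is drawn with probability
    proportional to its remaining count, excluding the previous label,
    with a forced pick whenever one label holds more than half of the
    remaining slots (the only way to stay feasible).  Index order within a
    label is randomized.
    """
    labels_arr = np.asarray(labels)
    n = len(labels_arr)
    uniq, counts0 = np.unique(labels_arr, return_counts=True)
    if counts0.max() > (n + 1) // 2:
        raise ScheduleError(
            f"word occurring {counts0.max()} times in a {n}-trial block cannot "
            "avoid consecutive repetitions"
        )
    for _ in range(max_tries):
        pools = [rng.permutation(np.where(labels_arr == lab)[0]).tolist()
                 for lab in uniq]
        counts = counts0.copy()
        prev = -1
        out = []
        ok = True
        for remaining in range(n, 0, -1):
            must = np.where(counts > remaining // 2)[0]
            if len(must) and counts[must[0]] > (remaining + 1) // 2:
                ok = False
                break
            if len(must) and must[0] != prev:
                choice = must[0]
            else:
                weights = counts.astype(float)
                if prev >= 0:
                    weights[prev] = 0.0
                total = weights.sum()
                if total == 0:
                    ok = False
                    break
                choice = rng.choice(len(uniq), p=weights / total)
            out.append(pools[choice].pop())
            counts[choice] -= 1
            prev = choice
        if ok:
            return np.array(out)
    raise ScheduleError("could not find a repeat-free ordering")  # pragma: no cover


def _block_trials(design: ExperimentDesign, language: str, block_index: int,
                  rng: np.random.Generator) -> pd.DataFrame:
    """Unordered trial set for one block, with balanced speaker assignment."""
    rows = []
    for c_i, concept in enumerate(design.concepts):
        wf = design.word_form(concept, language)
        for rep in range(design.reps_per_block):
            # cycle speakers so each word x speaker count is as even as
            # possible; with 6 reps and 3 speakers each pairing occurs twice
            speaker = (rep + c_i + block_index) % design.n_speakers
            rows.append((language, wf, concept, speaker, False))
    na_words = design.nonanimal_words[language]
    reps_na = design.nonanimal_trials_per_block // len(na_words) if na_words else 0
    for w_i, word in enumerate(na_words):
        for rep in range(reps_na):
            speaker = (rep + w_i + block_index) % design.n_speakers
            rows.append((language, word, "", speaker, True))
    return pd.DataFrame(
        rows, columns=["language", "word_form", "concept", "speaker", "is_target"]
    )


def build_schedule(design: ExperimentDesign, seed: int) -> TrialSchedule:
    """Build the pseudo-randomized session schedule.

    Within every block the trial order is drawn uniformly at random subject
    to the constraint that the same word form never occurs on consecutive
    trials.  Onsets follow a jittered inter-trial interval drawn uniformly
    from ``design.iti_range_s``.  Deterministic given ``seed``.

    Raises
    ------
    ScheduleError
        If the block composition makes the no-repeat constraint infeasible.
    """
    rng = np.random.default_rng([seed, 0x5EED])
    blocks = []
    block_counter = 0
    for run in range(1, design.n_runs + 1):
        for block in range(1, design.blocks_per_run + 1):
            language = _block_language(run, block)
            trials = _block_trials(design, language, block_counter, rng)
            order = _order_without_repeats(list(trials["word_form"]), rng)
            trials = trials.iloc[order].reset_index(drop=True)
            itis = rng.uniform(*design.iti_range_s, size=len(trials))
            onsets = 2.0 + np.concatenate([[0.0], np.cumsum(itis[:-1])])
            trials.insert(0, "run", run)
            trials.insert(1, "block", block)
            trials["onset_s"] = onsets
            blocks.append(trials)
            block_counter += 1
    table = pd.concat(blocks, ignore_index=True)
    return TrialSchedule(trials=table, design=design)
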