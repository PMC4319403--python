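"""Phoneme-level normalized Levenshtein distances between stimulus words.

The distance between two words is the minimal number of phoneme
insertions, deletions and substitutions turning one transcription into the
other, divided by the phoneme count of the longer word, so 0 means
identical and 1 means maximally different.  Transcriptions are data, not
computed: the packaged fixture uses broad, non-rhotic British-style
English transcriptions (no coda /r/ in "horse"/"shark") and broad standard
Dutch ones; with this convention every English-Dutch stimulus pair is
maximally distant (mean 1.00, SD 0.00).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from itertools import combinations
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Transcription",
    "levenshtein",
    "normalized_distance",
    "stimulus_summary",
    "load_stimulus_transcriptions",
    "pairwise_distances",
]


@dataclass(frozen=True)
class Transcription:
    """A word's broad phonemic transcription."""

    word: str
    language: str
    phonemes: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.phonemes:
            raise ValueError(f"empty transcription for {self.word!r}")


def levenshtein(a: Sequence, b: Sequence) -> int:
    """Minimal edit count (insertions, deletions, substitutions) between two
    symbol sequences, by dynamic programming.  Symmetric."""
    n, m = len(a), len(b)
    prev = list(range(m + 1))
    for i in range(1, n + 1):
        cur = [i] + [0] * m
        ai = a[i - 1]
        for j in range(1, m + 1):
            cost = 0 if ai == b[j - 1] else 1
            cur[j] = min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + cost)
        prev = cur
    return prev[m]


def normalized_distance(a: Transcription, b: Transcription) -> float:
    """Levenshtein distance divided by the longer word's phoneme count."""
    return levenshtein(a.phonemes, b.phonemes) / max(len(a.phonemes),
                                                     len(b.phonemes))


def load_stimulus_transcriptions(path: str | Path | None = None) -> list[Transcription]:
    """Load transcriptions from a TSV table (word, language, phonemes with
    space-separated symbols); defaults to the packaged stimulus fixture."""
    if path is None:
        source = resources.files("worddecode.data") / "stimuli.tsv"
        with resources.as_file(source) as p:
            table = pd.read_csv(p, sep="\t", comment="#")
    else:
        table = pd.read_csv(path, sep="\t", comment="#")
    return [
        Transcription(word=row.word, language=row.language,
                      phonemes=tuple(str(row.phonemes).split()))
        for row in table.itertuples(index=False)
    ]


def pairwise_distances(transcriptions: list[Transcription]) -> pd.DataFrame:
    """Normalized distances for every unordered pair, with a ``group``
    column: ``dutch`` / ``english`` for within-language pairs, ``cross``
    for English-Dutch pairs."""
    rows = []
    for t_a, t_b in combinations(transcriptions, 2):
        group = t_a.language if t_a.language == t_b.language else "cross"
        rows.append(
            dict(word_a=t_a.word, word_b=t_b.word, group=group,
                 distance=normalized_distance(t_a, t_b))
        )
    return pd.DataFrame(rows)


def stimulus_summary(transcriptions: list[Transcription],
                     n_per_language: int = 4) -> pd.DataFrame:
    """Mean and SD of normalized distances per group.

    Within-language groups hold the C(4,2) = 6 pairs of that language's
    animal nouns; the cross group holds all 4 x 4 = 16 English-Dutch pairs
    (with SD 0 this coincides with the 4 translation pairs alone).  SDs use
    ddof = 1.
    """
    by_lang: dict[str, int] = {}
    for t in transcriptions:
        by_lang[t.language] = by_lang.get(t.language, 0) + 1
    if any(n != n_per_language for n in by_lang.values()) or len(by_lang) != 2:
        raise ValueError(
            f"expected {n_per_language} words in each of 2 languages, got {by_lang}"
        )
    dists = pairwise_distances(transcriptions)
    out = (
        dists.groupby("group")["distance"]
        .agg(mean="mean", sd=lambda x: np.std(x, ddof=1), n="count")
        .reset_index()
    )
    return out
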