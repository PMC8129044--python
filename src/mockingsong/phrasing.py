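"""Grouping syllables into phrases (trains of repeated syllables).

Phrases come either from user annotations (a label track or CSV delimiting
each phrase) or, absent annotations, from a gap heuristic: a new phrase
starts whenever the silent gap between consecutive syllables reaches
``phrase_gap_ms``. Inter-syllable minibreaths are tens of milliseconds while
inter-phrase pauses are several hundred, so a single gap threshold separates
the two scales.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .errors import InputError
from .segment import Syllable, read_label_file

__all__ = [
    "Phrase",
    "DEFAULT_PHRASE_GAP_MS",
    "read_annotations",
    "group_into_phrases",
    "assign_syllables_to_phrases",
    "phrases_to_frame",
]

logger = logging.getLogger(__name__)

DEFAULT_PHRASE_GAP_MS = 250


@dataclass(frozen=True)
class Phrase:
    """An ordered train of syllables at one position in the song."""

    index: int
    syllables: list[Syllable]
    label: str | None = None

    def __post_init__(self) -> None:
        if not self.syllables:
            raise InputError(f"phrase {self.index} has no syllables")
        onsets = [s.onset_ms for s in self.syllables]
        if onsets != sorted(onsets):
            raise InputError(f"phrase {self.index}: syllables not sorted by onset")

    @property
    def onset_ms(self) -> int:
        return self.syllables[0].onset_ms

    @property
    def offset_ms(self) -> int:
        return self.syllables[-1].offset_ms

    @property
    def mean_syllable_duration_ms(self) -> float:
        return sum(s.duration_ms for s in self.syllables) / len(self.syllables)

    def __len__(self) -> int:
        return len(self.syllables)


def read_annotations(path: str | Path) -> list[tuple[int, int, str]]:
    """Read phrase intervals as (onset_ms, offset_ms, label), sorted.

    Accepts a tab-separated label track (start_s, end_s, label) or a CSV
    with columns start/end (seconds) or onset_ms/offset_ms, plus an optional
    label column. Overlapping intervals are an error.
    """
    path = Path(path)
    if path.suffix.lower() == ".csv":
        df = pd.read_csv(path)
        if df.empty:
            return []
        if {"onset_ms", "offset_ms"} <= set(df.columns):
            rows = [
                (int(r.onset_ms), int(r.offset_ms), str(getattr(r, "label", "")))
                for r in df.itertuples()
            ]
        elif {"start", "end"} <= set(df.columns):
            rows = [
                (int(round(r.start * 1000)), int(round(r.end * 1000)),
                 str(getattr(r, "label", "")))
                for r in df.itertuples()
            ]
        else:
            raise InputError(f"{path}: need columns onset_ms/offset_ms or start/end")
    else:
        rows = [
            (int(round(s * 1000)), int(round(e * 1000)), label)
            for s, e, label in read_label_file(path)
        ]
    for onset, offset, _ in rows:
        if offset <= onset:
            raise InputError(f"{path}: interval end {offset} ms <= start {onset} ms")
    rows.sort()
    for (a0, a1, _), (b0, _, _) in zip(rows, rows[1:]):
        if b0 < a1:
            raise InputError(f"{path}: phrase intervals overlap near {b0} ms")
    return rows


def group_into_phrases(
    syllables: list[Syllable], phrase_gap_ms: int = DEFAULT_PHRASE_GAP_MS
) -> list[Phrase]:
    """Split syllables into phrases wherever the inter-syllable gap >= phrase_gap_ms."""
    if not syllables:
        return []
    groups: list[list[Syllable]] = [[syllables[0]]]
    for prev, cur in zip(syllables, syllables[1:]):
        if cur.onset_ms - prev.offset_ms >= phrase_gap_ms:
            groups.append([cur])
        else:
            groups[-1].append(cur)
    return [Phrase(index=i, syllables=g) for i, g in enumerate(groups)]


def assign_syllables_to_phrases(
    syllables: list[Syllable], intervals: list[tuple[int, int, str]]
) -> list[Phrase]:
    """Assign each syllable to the annotated interval containing its onset.

    Syllables outside every interval are dropped with a logged warning.
    Intervals that end up empty are dropped too, so phrase indices stay
    consecutive.
    """
    intervals = sorted(intervals)
    for (a0, a1, _), (b0, _, _) in zip(intervals, intervals[1:]):
        if b0 < a1:
            raise InputError(f"annotated phrase intervals overlap near {b0} ms")
    buckets: list[list[Syllable]] = [[] for _ in intervals]
    dropped = 0
    for syl in syllables:
        for i, (onset, offset, _) in enumerate(intervals):
            if onset <= syl.onset_ms < offset:
                buckets[i].append(syl)
                break
        else:
            dropped += 1
            logger.warning(
                "syllable [%d, %d) falls outside all annotated phrases; dropped",
                syl.onset_ms, syl.offset_ms,
            )
    if dropped:
        logger.warning("%d syllable(s) dropped outside annotations", dropped)
    phrases = []
    for (onset, offset, label), bucket in zip(intervals, buckets):
        if bucket:
            phrases.append(Phrase(index=len(phrases), syllables=bucket, label=label or None))
    return phrases


def phrases_to_frame(phrases: list[Phrase]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "phrase_index": [p.index for p in phrases],
            "onset_ms": [p.onset_ms for p in phrases],
            "offset_ms": [p.offset_ms for p in phrases],
            "n_syllables": [len(p) for p in phrases],
            "label": [p.label or "" for p in phrases],
        }
    )
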