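"""Syllable segmentation by a combined amplitude / Wiener-entropy threshold.

A millisecond belongs to a syllable when the (normalised) amplitude envelope
is *louder* than the amplitude threshold AND the Wiener entropy is *lower*
(more tone-like) than the entropy threshold. Runs separated by gaps shorter
than ``min_gap_ms`` are merged (minibreath-scale dropouts), and runs shorter
than ``min_dur_ms`` are discarded as chatter.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InputError
from .features import FeatureTrack

__all__ = [
    "SyllableSegment",
    "Syllable",
    "segment_syllables",
    "auto_thresholds",
    "extract_syllables",
    "write_segments_csv",
    "read_segments_csv",
    "write_label_file",
    "read_label_file",
]

DEFAULT_AMP_THRESHOLD = 0.1
# below every voiced syllable (noisy high-pitched syllables measure about
# -0.8, tonal ones -5 or lower) yet above broadband background noise (-0.25);
# a large margin also keeps boundary trimming by mixed edge frames small
DEFAULT_ENT_THRESHOLD = -0.5
DEFAULT_MIN_DUR_MS = 10
DEFAULT_MIN_GAP_MS = 5


@dataclass(frozen=True, order=True)
class SyllableSegment:
    """Half-open millisecond interval [onset_ms, offset_ms)."""

    onset_ms: int
    offset_ms: int

    def __post_init__(self) -> None:
        if not (0 <= self.onset_ms < self.offset_ms):
            raise InputError(
                f"invalid segment [{self.onset_ms}, {self.offset_ms}): need 0 <= onset < offset"
            )

    @property
    def duration_ms(self) -> int:
        return self.offset_ms - self.onset_ms


@dataclass(frozen=True)
class Syllable:
    """A segmented sound unit with its three per-ms feature contours."""

    segment: SyllableSegment
    amp: np.ndarray
    freq: np.ndarray
    ent: np.ndarray

    def __post_init__(self) -> None:
        for name in ("amp", "freq", "ent"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=np.float64))
        n = self.segment.duration_ms
        if not (len(self.amp) == len(self.freq) == len(self.ent) == n):
            raise InputError(
                f"contour lengths {len(self.amp)}/{len(self.freq)}/{len(self.ent)} "
                f"do not match segment duration {n}"
            )

    @property
    def onset_ms(self) -> int:
        return self.segment.onset_ms

    @property
    def offset_ms(self) -> int:
        return self.segment.offset_ms

    @property
    def duration_ms(self) -> int:
        return self.segment.duration_ms


def auto_thresholds(
    amp: FeatureTrack, ent: FeatureTrack, amp_q: float = 0.60, ent_q: float = 0.40
) -> tuple[float, float]:
    """Percentile-based thresholds for unattended use.

    Amplitude threshold = the ``amp_q`` quantile of the envelope; entropy
    threshold = the ``ent_q`` quantile of the entropy track.
    """
    return float(np.quantile(amp.values, amp_q)), float(np.quantile(ent.values, ent_q))


def segment_syllables(
    amp: FeatureTrack,
    ent: FeatureTrack,
    amp_threshold: float = DEFAULT_AMP_THRESHOLD,
    ent_threshold: float = DEFAULT_ENT_THRESHOLD,
    min_dur_ms: int = DEFAULT_MIN_DUR_MS,
    min_gap_ms: int = DEFAULT_MIN_GAP_MS,
) -> list[SyllableSegment]:
    """Maximal runs where amp > amp_threshold and entropy < ent_threshold.

    Gaps shorter than ``min_gap_ms`` between runs are bridged; runs shorter
    than ``min_dur_ms`` after merging are dropped. Returned sorted and
    non-overlapping.
    """
    if len(amp) != len(ent) or amp.start_ms != ent.start_ms:
        raise InputError(
            f"amplitude ({len(amp)} ms @ {amp.start_ms}) and entropy "
            f"({len(ent)} ms @ {ent.start_ms}) tracks do not share a time base"
        )
    if not (np.isfinite(amp_threshold) and np.isfinite(ent_threshold)):
        raise InputError("thresholds must be finite")
    mask = (amp.values > amp_threshold) & (ent.values < ent_threshold)
    runs = _mask_runs(mask)
    runs = _merge_gaps(runs, min_gap_ms)
    offset = amp.start_ms
    return [
        SyllableSegment(int(a) + offset, int(b) + offset)
        for a, b in runs
        if b - a >= min_dur_ms
    ]


def _mask_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    edges = np.flatnonzero(np.diff(np.concatenate(([False], mask, [False])).astype(np.int8)))
    return list(zip(edges[::2], edges[1::2]))


def _merge_gaps(runs: list[tuple[int, int]], min_gap_ms: int) -> list[tuple[int, int]]:
    if not runs:
        return []
    merged = [list(runs[0])]
    for a, b in runs[1:]:
        if a - merged[-1][1] < min_gap_ms:
            merged[-1][1] = b
        else:
            merged.append([a, b])
    return [(a, b) for a, b in merged]


def extract_syllables(
    segments: list[SyllableSegment],
    amp: FeatureTrack,
    freq: FeatureTrack,
    ent: FeatureTrack,
) -> list[Syllable]:
    """Cut the three contours on each segment's [onset, offset) interval."""
    return [
        Syllable(
            segment=seg,
            amp=amp.slice_ms(seg.onset_ms, seg.offset_ms),
            freq=freq.slice_ms(seg.onset_ms, seg.offset_ms),
            ent=ent.slice_ms(seg.onset_ms, seg.offset_ms),
        )
        for seg in segments
    ]


def write_segments_csv(path: str | Path, segments: list[SyllableSegment]) -> None:
    pd.DataFrame(
        {"onset_ms": [s.onset_ms for s in segments], "offset_ms": [s.offset_ms for s in segments]}
    ).to_csv(path, index=False)


def read_segments_csv(path: str | Path) -> list[SyllableSegment]:
    df = pd.read_csv(path)
    return [SyllableSegment(int(r.onset_ms), int(r.offset_ms)) for r in df.itertuples()]


def write_label_file(
    path: str | Path, segments: list[SyllableSegment], labels: list[str] | None = None
) -> None:
    """Audacity-style label track: start_s<TAB>end_s<TAB>label."""
    labels = labels or [""] * len(segments)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        for seg, label in zip(segments, labels):
            writer.writerow([f"{seg.onset_ms / 1000:.3f}", f"{seg.offset_ms / 1000:.3f}", label])


def read_label_file(path: str | Path) -> list[tuple[float, float, str]]:
    """Read a tab-separated label track as (start_s, end_s, label) tuples."""
    out: list[tuple[float, float, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise InputError(f"{path}:{lineno}: expected at least start<TAB>end")
            start, end = float(parts[0]), float(parts[1])
            if end < start:
                raise InputError(f"{path}:{lineno}: end {end} < start {start}")
            out.append((start, end, parts[2] if len(parts) > 2 else ""))
    return out
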