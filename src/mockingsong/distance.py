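"""DTW syllable distances with warping-path transfer.

Two syllables are compared by dynamic time warping of their *amplitude
envelopes* (absolute-difference cost, step set {(1,0),(0,1),(1,1)}, no band
constraint). The optimal warping path found on the envelopes is then reused
verbatim on the frequency and entropy contours, so all three features are
compared under one temporal alignment. Each feature's distance is the mean
over warping-path steps of the pointwise absolute difference; durations,
being scalars, are compared as shorter:longer ratio.

Phrase pairs are scored by averaging each field over all m x n pairwise
syllable comparisons between the two phrases.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit

from .errors import InputError
from .phrasing import Phrase
from .segment import Syllable

__all__ = [
    "WarpingPath",
    "PairDistance",
    "dtw_path",
    "warped_distance",
    "duration_ratio",
    "syllable_distance",
    "phrase_distance",
    "distances_to_frame",
]


@dataclass(frozen=True)
class WarpingPath:
    """Monotone alignment between two sequences.

    ``steps`` is an (L, 2) integer array of (i, j) index pairs running from
    (0, 0) to (lenA-1, lenB-1); each step advances i, j, or both by 1.
    """

    steps: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "steps", np.asarray(self.steps, dtype=np.int64))

    def __len__(self) -> int:
        return len(self.steps)

    def validate(self, len_a: int, len_b: int) -> None:
        s = self.steps
        if len(s) == 0 or tuple(s[0]) != (0, 0) or tuple(s[-1]) != (len_a - 1, len_b - 1):
            raise InputError("warping path must run from (0,0) to (lenA-1, lenB-1)")
        d = np.diff(s, axis=0)
        if not (np.all(d >= 0) and np.all(d <= 1) and np.all(d.sum(axis=1) >= 1)):
            raise InputError("warping path steps must advance i, j, or both by exactly 1")


@dataclass(frozen=True)
class PairDistance:
    """Four-metric comparison of a syllable pair or phrase pair.

    ``n_comparisons`` is 1 for a syllable pair and m*n for a phrase pair.
    """

    amp_dist: float
    freq_dist: float
    ent_dist: float
    dur_ratio: float
    n_comparisons: int = 1

    def __post_init__(self) -> None:
        vals = (self.amp_dist, self.freq_dist, self.ent_dist, self.dur_ratio)
        if not all(np.isfinite(v) for v in vals):
            raise InputError(f"distance fields must be finite, got {vals}")
        if min(self.amp_dist, self.freq_dist, self.ent_dist) < 0:
            raise InputError("distances must be non-negative")
        if not (0 < self.dur_ratio <= 1 + 1e-12):
            raise InputError(f"dur_ratio must lie in (0, 1], got {self.dur_ratio}")


@njit(cache=False)
def _dtw_core(a: np.ndarray, b: np.ndarray):  # pragma: no cover - exercised via dtw_path
    n, m = a.shape[0], b.shape[0]
    acc = np.empty((n, m))
    acc[0, 0] = abs(a[0] - b[0])
    for i in range(1, n):
        acc[i, 0] = acc[i - 1, 0] + abs(a[i] - b[0])
    for j in range(1, m):
        acc[0, j] = acc[0, j - 1] + abs(a[0] - b[j])
    for i in range(1, n):
        ai = a[i]
        for j in range(1, m):
            best = acc[i - 1, j - 1]
            if acc[i - 1, j] < best:
                best = acc[i - 1, j]
            if acc[i, j - 1] < best:
                best = acc[i, j - 1]
            acc[i, j] = best + abs(ai - b[j])
    # backtrack, preferring diagonal, then vertical (i-1, j), then horizontal
    path_i = np.empty(n + m, dtype=np.int64)
    path_j = np.empty(n + m, dtype=np.int64)
    k = n + m - 1
    i, j = n - 1, m - 1
    path_i[k] = i
    path_j[k] = j
    while i > 0 or j > 0:
        if i == 0:
            j -= 1
        elif j == 0:
            i -= 1
        else:
            diag = acc[i - 1, j - 1]
            vert = acc[i - 1, j]
            horiz = acc[i, j - 1]
            best = min(diag, vert, horiz)
            if diag == best:
                i -= 1
                j -= 1
            elif vert == best:
                i -= 1
            else:
                j -= 1
        k -= 1
        path_i[k] = i
        path_j[k] = j
    return acc[n - 1, m - 1], path_i[k:], path_j[k:]


def dtw_path(a: np.ndarray, b: np.ndarray) -> tuple[WarpingPath, float]:
    """Optimal warping path and total cost between two 1-D sequences.

    Cost is the sum of |a[i] - b[j]| over path steps; ties in backtracking
    are broken diagonal-first for determinism.
    """
    a = np.ascontiguousarray(a, dtype=np.float64)
    b = np.ascontiguousarray(b, dtype=np.float64)
    if a.size == 0 or b.size == 0:
        raise InputError("dtw_path requires non-empty sequences")
    cost, pi, pj = _dtw_core(a, b)
    return WarpingPath(np.stack([pi, pj], axis=1)), float(cost)


def warped_distance(path: WarpingPath, fa: np.ndarray, fb: np.ndarray) -> float:
    """Mean |fa[i] - fb[j]| over the steps of an existing warping path."""
    fa = np.asarray(fa, dtype=np.float64)
    fb = np.asarray(fb, dtype=np.float64)
    i, j = path.steps[:, 0], path.steps[:, 1]
    if len(path) == 0 or i.max() >= len(fa) or j.max() >= len(fb) or i.min() < 0 or j.min() < 0:
        raise InputError(
            f"path indices exceed contour lengths ({len(fa)}, {len(fb)})"
        )
    return float(np.mean(np.abs(fa[i] - fb[j])))


def duration_ratio(dur_a: float, dur_b: float) -> float:
    """Shorter duration over longer duration, in (0, 1]."""
    if dur_a <= 0 or dur_b <= 0:
        raise InputError(f"durations must be positive, got ({dur_a}, {dur_b})")
    return float(min(dur_a, dur_b) / max(dur_a, dur_b))


def syllable_distance(sa: Syllable, sb: Syllable) -> PairDistance:
    """Four-metric distance between two syllables.

    DTW runs on the amplitude envelopes; the resulting path is transferred
    unchanged to the frequency and entropy contours.
    """
    path, _ = dtw_path(sa.amp, sb.amp)
    return PairDistance(
        amp_dist=warped_distance(path, sa.amp, sb.amp),
        freq_dist=warped_distance(path, sa.freq, sb.freq),
        ent_dist=warped_distance(path, sa.ent, sb.ent),
        dur_ratio=duration_ratio(sa.duration_ms, sb.duration_ms),
    )


def phrase_distance(pa: Phrase, pb: Phrase) -> PairDistance:
    """All-pairs phrase score: each field averaged over the m*n syllable pairs."""
    if not pa.syllables or not pb.syllables:
        raise InputError("phrase_distance requires non-empty phrases")
    pairs = [syllable_distance(sa, sb) for sa in pa.syllables for sb in pb.syllables]
    n = len(pairs)
    return PairDistance(
        amp_dist=sum(p.amp_dist for p in pairs) / n,
        freq_dist=sum(p.freq_dist for p in pairs) / n,
        ent_dist=sum(p.ent_dist for p in pairs) / n,
        dur_ratio=sum(p.dur_ratio for p in pairs) / n,
        n_comparisons=n,
    )


def distances_to_frame(rows: list[tuple[int, int, PairDistance]]) -> pd.DataFrame:
    """Tabulate (phrase_a, phrase_b, PairDistance) triples as a CSV-ready frame."""
    return pd.DataFrame(
        {
            "phrase_a": [a for a, _, _ in rows],
            "phrase_b": [b for _, b, _ in rows],
            "n_comparisons": [d.n_comparisons for _, _, d in rows],
            "amp_dist": [d.amp_dist for _, _, d in rows],
            "freq_dist": [d.freq_dist for _, _, d in rows],
            "ent_dist": [d.ent_dist for _, _, d in rows],
            "dur_ratio": [d.dur_ratio for _, _, d in rows],
        }
    )
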