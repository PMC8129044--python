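import numpy as np
import pytest

from mockingsong import AudioClip
from mockingsong.segment import Syllable, SyllableSegment


@pytest.fixture
def tone_clip():
    """Factory for pure/multi-tone test clips."""

    def make(freqs=(2000.0,), duration_s=1.0, sample_rate=44100, amplitude=1.0):
        t = np.arange(int(duration_s * sample_rate)) / sample_rate
        x = sum(np.sin(2 * np.pi * f * t) for f in freqs)
        x = amplitude * x / len(freqs)
        return AudioClip(samples=x, sample_rate=sample_rate)

    return make


def make_syllable(onset_ms, amp, freq=None, ent=None):
    """Build a syllable directly from contour arrays (no audio involved)."""
    amp = np.asarray(amp, dtype=float)
    n = len(amp)
    freq = np.asarray(freq, dtype=float) if freq is not None else np.full(n, 2000.0)
    ent = np.asarray(ent, dtype=float) if ent is not None else np.full(n, -5.0)
    return Syllable(SyllableSegment(onset_ms, onset_ms + n), amp, freq, ent)


def brute_force_dtw_cost(a, b):
    """Exhaustive minimum cost over all admissible warping paths.

    Enumerates every monotone path from (0,0) to (n-1,m-1) with steps
    {(1,0),(0,1),(1,1)} by depth-first search — independent of the DP
    implementation under test. Only viable for short sequences.
    """
    n, m = len(a), len(b)
    best = [float("inf")]

    def walk(i, j, cost):
        cost += abs(a[i] - b[j])
        if cost >= best[0]:
            return
        if i == n - 1 and j == m - 1:
            best[0] = cost
            return
        if i + 1 < n and j + 1 < m:
            walk(i + 1, j + 1, cost)
        if i + 1 < n:
            walk(i + 1, j, cost)
        if j + 1 < m:
            walk(i, j + 1, cost)

    walk(0, 0, 0.0)
    return best[0]
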