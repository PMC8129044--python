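"""Per-millisecond acoustic feature contours.

Three contours are extracted on a shared 0-based, half-open, 1 ms grid:

* **amplitude envelope** — RMS of the waveform in a 10 ms window centred on
  each millisecond, optionally max-normalised within consecutive 4 s windows
  so that slow gain drift (e.g. a singing bird turning its head) does not
  enter the amplitude distance measure;
* **mean frequency** — the power-weighted spectral centroid per frame, a
  pitch measure tracking the centre of mass of the power spectrum;
* **Wiener entropy** — log10 spectral flatness (geometric over arithmetic
  mean of the power spectrum), a timbre measure: 0 for a flat (white-noise)
  spectrum, strongly negative for tone-like sounds.

Spectral frames are ~10 ms, Hann-windowed, zero-padded to the next power of
two. Frames of digital silence get the entropy floor (-10) and a 0 Hz
frequency fill; segmentation guarantees neither fill ever enters a distance.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.fft import rfft, rfftfreq
from scipy.ndimage import uniform_filter1d
from scipy.signal import get_window

from .audio import AudioClip
from .errors import InputError

__all__ = [
    "FeatureTrack",
    "amplitude_envelope",
    "normalize_envelope",
    "wiener_entropy",
    "mean_frequency",
    "wiener_entropy_from_power",
    "spectral_centroid_from_power",
    "feature_tracks",
    "tracks_to_frame",
    "write_feature_csv",
]

FRAME_MS = 10
NORM_WINDOW_MS = 4000
ENTROPY_FLOOR = -10.0
SILENT_FREQ_FILL = 0.0
_POWER_EPS = 1e-30  # floor for log of near-empty spectral bins
_SILENCE_POWER = 1e-24  # total frame power below this counts as digital silence

_KINDS = ("amplitude", "frequency", "entropy")


@dataclass(frozen=True)
class FeatureTrack:
    """One acoustic feature sampled every millisecond.

    ``values[t]`` describes the millisecond ``[start_ms + t, start_ms + t + 1)``.
    """

    kind: str
    values: np.ndarray
    start_ms: int = 0

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise InputError(f"unknown feature kind {self.kind!r}; expected one of {_KINDS}")
        object.__setattr__(self, "values", np.asarray(self.values, dtype=np.float64))

    def __len__(self) -> int:
        return len(self.values)

    def slice_ms(self, onset_ms: int, offset_ms: int) -> np.ndarray:
        """Values on the half-open interval [onset_ms, offset_ms)."""
        lo = onset_ms - self.start_ms
        hi = offset_ms - self.start_ms
        if lo < 0 or hi > len(self.values) or lo >= hi:
            raise InputError(
                f"interval [{onset_ms}, {offset_ms}) outside track range "
                f"[{self.start_ms}, {self.start_ms + len(self.values)})"
            )
        return self.values[lo:hi]


def _n_ms(clip: AudioClip) -> int:
    return int(len(clip.samples) * 1000 // clip.sample_rate)


def _ms_centers(clip: AudioClip, n_ms: int) -> np.ndarray:
    """Sample index of the centre of each millisecond bin."""
    c = np.round((np.arange(n_ms) + 0.5) * clip.sample_rate / 1000.0).astype(np.int64)
    return np.clip(c, 0, len(clip.samples) - 1)


def amplitude_envelope(clip: AudioClip) -> FeatureTrack:
    """Un-normalised RMS envelope: 10 ms windows, 1 ms steps.

    Windows are centred on each millisecond; edges are zero-padded, so the
    first/last few values taper toward zero.
    """
    win = int(round(FRAME_MS * clip.sample_rate / 1000.0))
    n_ms = _n_ms(clip)
    if n_ms < FRAME_MS:
        raise InputError(
            f"clip of {clip.duration_ms:.1f} ms is shorter than one {FRAME_MS} ms window"
        )
    mean_sq = uniform_filter1d(clip.samples ** 2, size=win, mode="constant", cval=0.0)
    env = np.sqrt(np.maximum(mean_sq[_ms_centers(clip, n_ms)], 0.0))
    return FeatureTrack("amplitude", env)


def normalize_envelope(env: FeatureTrack, window_ms: int = NORM_WINDOW_MS) -> FeatureTrack:
    """Divide the envelope by its maximum within consecutive windows.

    Windows tile the track contiguously from t=0; the last partial window is
    normalised by its own maximum; an all-zero window stays all-zero. Output
    is in [0, 1] and invariant to any uniform positive gain applied within a
    window.
    """
    if env.kind != "amplitude":
        raise InputError("normalize_envelope expects an amplitude track")
    values = env.values.copy()
    for start in range(0, len(values), window_ms):
        chunk = values[start:start + window_ms]
        peak = chunk.max(initial=0.0)
        if peak > 0:
            chunk /= peak
    return replace(env, values=values)


def _frame_power(clip: AudioClip, chunk: slice | None = None):
    """Hann-windowed power spectra of ~10 ms frames centred on each ms."""
    win = int(round(FRAME_MS * clip.sample_rate / 1000.0))
    n_ms = _n_ms(clip)
    if n_ms < 1 or len(clip.samples) < win:
        raise InputError("clip shorter than one analysis frame")
    nfft = 1 << (win - 1).bit_length()
    window = get_window("hann", win, fftbins=True)
    centers = _ms_centers(clip, n_ms)
    if chunk is not None:
        centers = centers[chunk]
    pad = win // 2 + 1
    padded = np.pad(clip.samples, pad)
    idx = (centers + pad - win // 2)[:, None] + np.arange(win)[None, :]
    frames = padded[idx] * window
    power = np.abs(rfft(frames, n=nfft, axis=1)) ** 2
    freqs = rfftfreq(nfft, d=1.0 / clip.sample_rate)
    return power, freqs, n_ms


def wiener_entropy_from_power(power: np.ndarray) -> np.ndarray:
    """log10(geometric mean / arithmetic mean) of power spectra (rows).

    0 for a flat spectrum, negative otherwise; silent frames get the
    configured floor. Accepts a single spectrum or a stack of spectra.
    """
    p = np.atleast_2d(np.asarray(power, dtype=np.float64))
    total = p.sum(axis=1)
    amean = total / p.shape[1]
    # log10 throughout so a flat spectrum cancels exactly to 0
    log_g = np.mean(np.log10(np.maximum(p, _POWER_EPS)), axis=1)
    with np.errstate(divide="ignore"):
        ent = log_g - np.log10(np.maximum(amean, _POWER_EPS))
    ent = np.clip(ent, ENTROPY_FLOOR, 0.0)
    ent[ent > -1e-12] = 0.0  # snap round-off so a flat spectrum is exactly 0
    ent[total < _SILENCE_POWER] = ENTROPY_FLOOR
    return ent if np.asarray(power).ndim > 1 else ent[0]


def spectral_centroid_from_power(power: np.ndarray, freqs: np.ndarray) -> np.ndarray:
    """Power-weighted mean frequency per spectrum row; 0 Hz on silence."""
    p = np.atleast_2d(np.asarray(power, dtype=np.float64))
    total = p.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cent = (p @ freqs) / total
    cent[~np.isfinite(cent) | (total < _SILENCE_POWER)] = SILENT_FREQ_FILL
    return cent if np.asarray(power).ndim > 1 else cent[0]


def wiener_entropy(clip: AudioClip) -> FeatureTrack:
    """Per-millisecond log Wiener entropy (spectral flatness), values <= 0."""
    return feature_tracks(clip, normalize=False)[2]


def mean_frequency(clip: AudioClip) -> FeatureTrack:
    """Per-millisecond spectral centroid in Hz, within [0, Nyquist]."""
    return feature_tracks(clip, normalize=False)[1]


def feature_tracks(
    clip: AudioClip,
    normalize: bool = True,
    chunk_ms: int = 20000,
) -> tuple[FeatureTrack, FeatureTrack, FeatureTrack]:
    """Compute (amplitude, frequency, entropy) tracks on one shared time base.

    The spectral frames are computed once and reused for both frequency and
    entropy; long recordings are processed in chunks to bound memory.
    """
    env = amplitude_envelope(clip)
    if normalize:
        env = normalize_envelope(env)
    n_ms = _n_ms(clip)
    cent = np.empty(n_ms)
    ent = np.empty(n_ms)
    for start in range(0, n_ms, chunk_ms):
        sl = slice(start, min(start + chunk_ms, n_ms))
        power, freqs, _ = _frame_power(clip, chunk=sl)
        cent[sl] = spectral_centroid_from_power(power, freqs)
        ent[sl] = wiener_entropy_from_power(power)
    return env, FeatureTrack("frequency", cent), FeatureTrack("entropy", ent)


def tracks_to_frame(tracks: Iterable[FeatureTrack]) -> pd.DataFrame:
    """Tabulate tracks as time_ms, amplitude, frequency_hz, wiener_entropy."""
    by_kind = {t.kind: t for t in tracks}
    missing = set(_KINDS) - set(by_kind)
    if missing:
        raise InputError(f"missing feature tracks: {sorted(missing)}")
    lengths = {k: len(t) for k, t in by_kind.items()}
    if len(set(lengths.values())) != 1:
        raise InputError(f"tracks differ in length: {lengths}")
    amp = by_kind["amplitude"]
    return pd.DataFrame(
        {
            "time_ms": np.arange(len(amp)) + amp.start_ms,
            "amplitude": amp.values,
            "frequency_hz": by_kind["frequency"].values,
            "wiener_entropy": by_kind["entropy"].values,
        }
    )


def write_feature_csv(path: str | Path, tracks: Iterable[FeatureTrack]) -> None:
    tracks_to_frame(tracks).to_csv(path, index=False)
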