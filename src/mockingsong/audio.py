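"""WAV input and the in-memory audio container.

Recordings are held as float64 arrays in the nominal range -1..1 regardless
of the on-disk sample format; multi-channel files are averaged to mono on
load because every downstream feature is defined on a single waveform.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.io import wavfile

from .errors import InputError

__all__ = ["AudioClip", "load_audio", "save_audio"]


@dataclass(frozen=True)
class AudioClip:
    """A mono recording: samples in -1..1 plus its sample rate in Hz."""

    samples: np.ndarray
    sample_rate: int

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        object.__setattr__(self, "samples", samples)
        if self.sample_rate <= 0:
            raise InputError(f"sample_rate must be positive, got {self.sample_rate}")
        if samples.ndim != 1:
            raise InputError("AudioClip holds mono audio (1-D sample array)")
        if samples.size == 0:
            raise InputError("AudioClip must contain at least one sample")
        if not np.all(np.isfinite(samples)):
            raise InputError("audio samples must all be finite")

    @property
    def duration_ms(self) -> float:
        return 1000.0 * len(self.samples) / self.sample_rate

    @property
    def nyquist(self) -> float:
        return self.sample_rate / 2.0


def load_audio(path: str | Path) -> AudioClip:
    """Read a PCM/float RIFF WAV file into a mono, -1..1 scaled clip.

    Multi-channel input is averaged across channels. Raises
    :class:`InputError` for missing, empty, or undecodable files.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"audio file not found: {path}")
    try:
        rate, data = wavfile.read(str(path))
    except Exception as exc:  # wavfile raises bare ValueError on corrupt input
        raise InputError(f"could not decode WAV file {path}: {exc}") from exc
    if data.size == 0:
        raise InputError(f"audio file is empty: {path}")
    if data.dtype == np.uint8:  # 8-bit WAV is unsigned, midpoint 128
        floats = (data.astype(np.float64) - 128.0) / 128.0
    elif data.dtype == np.int16:
        floats = data.astype(np.float64) / 2.0 ** 15
    elif data.dtype == np.int32:
        floats = data.astype(np.float64) / 2.0 ** 31
    else:  # float32 / float64 WAV already nominally -1..1
        floats = data.astype(np.float64)
    if floats.ndim == 2:
        floats = floats.mean(axis=1)
    return AudioClip(samples=floats, sample_rate=int(rate))


def save_audio(path: str | Path, clip: AudioClip) -> None:
    """Write a clip as 32-bit float WAV."""
    wavfile.write(str(path), clip.sample_rate, clip.samples.astype(np.float32))
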