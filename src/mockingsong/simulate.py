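"""Synthetic mockingbird-like song with ground truth.

Syllables are rendered as a harmonic stack (linear f0 glide, per-harmonic
rolloff) mixed with band-limited noise by a ``noisiness`` weight, under an
attack/sustain/decay amplitude shape. This parameterisation controls the
three measured feature axes independently: the amplitude envelope via the
shape, mean frequency via f0 and the harmonic stack, and Wiener entropy via
noisiness. Phrases repeat one template 3-5+ times separated by short
minibreath gaps; successive phrases are linked by a morph operator (pitch
shift, timbre change, temporal stretch/squeeze) or start from a fresh
template (contrast). Background white noise is added at a configurable SNR.

The generator returns the audio plus a full ground truth (syllable
intervals, phrase membership, per-transition mode), so every downstream
stage can be tested against known answers.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import butter, sosfilt

from .audio import AudioClip, save_audio
from .errors import InputError
from .features import feature_tracks
from .modes import MorphMode
from .segment import Syllable, SyllableSegment

__all__ = [
    "SyllableTemplate",
    "MorphParams",
    "SongSpec",
    "SongGroundTruth",
    "random_template",
    "render_syllable",
    "apply_morph",
    "generate_song",
    "generate_null_song",
    "syllable_from_template",
    "write_song",
]

logger = logging.getLogger(__name__)

DEFAULT_SAMPLE_RATE = 22050

# template sampling ranges: within reported mockingbird song characteristics
_DUR_RANGE_MS = (40, 250)
_F0_RANGE_HZ = (1000.0, 6000.0)
# clamps applied when chained morphs would walk out of the plausible range
_DUR_CLAMP_MS = (25, 400)
_F0_CLAMP_HZ = (600.0, 8500.0)


@dataclass(frozen=True)
class SyllableTemplate:
    """Parametric description of one syllable type."""

    duration_ms: int = 100
    f0_start_hz: float = 2000.0
    f0_end_hz: float = 2500.0
    n_harmonics: int = 3
    harmonic_rolloff_db: float = 8.0
    noisiness: float = 0.2
    attack_frac: float = 0.05
    decay_frac: float = 0.08
    n_notes: int = 1  # amplitude humps: 1 = uniform whistle, 2-3 = multi-note syllable

    def __post_init__(self) -> None:
        if self.duration_ms <= 0:
            raise InputError(f"duration_ms must be positive, got {self.duration_ms}")
        if min(self.f0_start_hz, self.f0_end_hz) <= 0:
            raise InputError("fundamental frequency must be positive")
        if not 0 <= self.noisiness <= 1:
            raise InputError(f"noisiness must lie in [0, 1], got {self.noisiness}")
        if self.n_harmonics < 1:
            raise InputError("need at least one harmonic")
        if self.attack_frac < 0 or self.decay_frac < 0 or self.attack_frac + self.decay_frac > 1:
            raise InputError("attack/decay fractions must be non-negative and sum to <= 1")
        if self.n_notes < 1:
            raise InputError("n_notes must be >= 1")

    @property
    def f0_max_hz(self) -> float:
        return max(self.f0_start_hz, self.f0_end_hz)


@dataclass(frozen=True)
class MorphParams:
    """Effect-size ranges the morph operators sample from."""

    pitch_factor_range: tuple[float, float] = (1.15, 1.35)
    duration_factor_range: tuple[float, float] = (1.6, 2.2)
    noisiness_delta_range: tuple[float, float] = (0.35, 0.6)
    rolloff_delta_db_range: tuple[float, float] = (4.0, 10.0)


@dataclass(frozen=True)
class SongSpec:
    """Structure and conditions of one simulated song bout."""

    n_phrases: int = 150
    reps_range: tuple[int, int] = (3, 5)
    mode_probabilities: dict[str, float] = field(
        default_factory=lambda: {
            "timbre": 0.2, "pitch": 0.2, "stretch": 0.2, "squeeze": 0.2, "contrast": 0.2,
        }
    )
    morph_params: MorphParams = field(default_factory=MorphParams)
    minibreath_ms: int = 30
    phrase_gap_ms: int = 400
    noise_snr_db: float = 25.0
    sample_rate: int = DEFAULT_SAMPLE_RATE
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_phrases < 1:
            raise InputError("n_phrases must be >= 1")
        lo, hi = self.reps_range
        if not (1 <= lo <= hi <= 20):
            raise InputError(f"reps_range must lie within 1..20, got {self.reps_range}")
        unknown = set(self.mode_probabilities) - {m.value for m in MorphMode}
        if unknown:
            raise InputError(f"unknown morph modes in probabilities: {sorted(unknown)}")
        total = sum(self.mode_probabilities.values())
        if abs(total - 1.0) > 1e-9:
            raise InputError(f"mode probabilities must sum to 1, got {total}")
        if self.minibreath_ms < 0 or self.phrase_gap_ms < 0:
            raise InputError("gap durations must be non-negative")


@dataclass(frozen=True)
class SongGroundTruth:
    """Everything a test needs: intervals, phrase membership, transitions."""

    syllable_intervals: list[SyllableSegment]
    phrase_of_syllable: list[int]
    transition_modes: list[MorphMode]
    templates: list[SyllableTemplate]
    duration_ms: int

    @property
    def n_phrases(self) -> int:
        return len(self.templates)

    @property
    def n_syllables(self) -> int:
        return len(self.syllable_intervals)


def random_template(rng: np.random.Generator) -> SyllableTemplate:
    """Draw an independent syllable type from the default plausible ranges."""
    f0 = rng.uniform(*_F0_RANGE_HZ)
    return SyllableTemplate(
        duration_ms=int(rng.integers(_DUR_RANGE_MS[0], _DUR_RANGE_MS[1] + 1)),
        f0_start_hz=f0,
        f0_end_hz=float(np.clip(f0 * rng.uniform(0.8, 1.25), *_F0_CLAMP_HZ)),
        n_harmonics=int(rng.integers(1, 5)),
        harmonic_rolloff_db=float(rng.uniform(4.0, 14.0)),
        noisiness=float(rng.uniform(0.0, 0.6)),
        attack_frac=float(rng.uniform(0.02, 0.08)),
        decay_frac=float(rng.uniform(0.03, 0.12)),
        n_notes=int(rng.integers(1, 4)),
    )


def render_syllable(
    t: SyllableTemplate,
    sample_rate: int = DEFAULT_SAMPLE_RATE,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Render one syllable as a waveform with peak amplitude 0.9.

    Harmonics whose frequency would exceed Nyquist anywhere in the glide are
    dropped with a log message; the noise component is band-passed around
    the harmonic band so that mixing in noise does not move the centroid far.
    """
    rng = rng or np.random.default_rng()
    nyquist = sample_rate / 2.0
    if t.f0_max_hz >= nyquist:
        raise InputError(f"f0 {t.f0_max_hz:.0f} Hz is at or above Nyquist {nyquist:.0f} Hz")
    n = int(round(t.duration_ms * sample_rate / 1000.0))
    time = np.arange(n) / sample_rate
    f0 = np.linspace(t.f0_start_hz, t.f0_end_hz, n)
    phase = 2 * np.pi * np.cumsum(f0) / sample_rate

    harmonic = np.zeros(n)
    kept_any = False
    for h in range(1, t.n_harmonics + 1):
        if h * t.f0_max_hz >= nyquist:
            logger.debug("harmonic %d above Nyquist; dropped", h)
            continue
        kept_any = True
        gain = 10 ** (-t.harmonic_rolloff_db * (h - 1) / 20.0)
        harmonic += gain * np.sin(h * phase)
    if not kept_any:
        logger.warning("all harmonics above Nyquist; syllable reduced to noise")

    # noise band hugs the harmonic stack so noisiness moves entropy (timbre)
    # much more than it moves the spectral centroid (pitch)
    lo = max(20.0, 0.7 * min(t.f0_start_hz, t.f0_end_hz))
    hi = min(0.95 * nyquist, 1.8 * t.f0_max_hz)
    sos = butter(4, [lo, max(hi, lo * 1.5)], btype="bandpass", fs=sample_rate, output="sos")
    noise = sosfilt(sos, rng.standard_normal(n))

    def _unit_rms(x: np.ndarray) -> np.ndarray:
        r = np.sqrt(np.mean(x ** 2))
        return x / r if r > 0 else x

    if t.noisiness >= 1.0 or not kept_any:
        wave = _unit_rms(noise)
    elif t.noisiness <= 0.0:
        wave = _unit_rms(harmonic)
    else:
        wave = (1 - t.noisiness) * _unit_rms(harmonic) + t.noisiness * _unit_rms(noise)

    wave = wave * _amplitude_shape(n, t.attack_frac, t.decay_frac, t.n_notes)
    peak = np.max(np.abs(wave))
    return wave * (0.9 / peak) if peak > 0 else wave


def _amplitude_shape(n: int, attack_frac: float, decay_frac: float, n_notes: int) -> np.ndarray:
    shape = np.ones(n)
    na = int(round(attack_frac * n))
    nd = int(round(decay_frac * n))
    if na > 0:
        shape[:na] = np.linspace(0.0, 1.0, na, endpoint=False)
    if nd > 0:
        shape[n - nd:] = np.linspace(1.0, 0.0, nd)
    if n_notes > 1:
        # multi-note syllables: n_notes humps separated by internal dips with
        # a raised floor. The modulation equals 1 at both edges so syllable
        # onset/offset stay governed by the attack/decay ramp alone, and the
        # segmenter neither splits at a dip nor mis-times the boundaries.
        x = np.arange(n) / max(n - 1, 1)
        shape *= 1.0 - 0.65 * np.sin(np.pi * (n_notes - 1) * x) ** 2
    return shape


def apply_morph(
    t: SyllableTemplate,
    mode: MorphMode,
    params: MorphParams | None = None,
    rng: np.random.Generator | None = None,
    sample_rate: int = DEFAULT_SAMPLE_RATE,
    clamp: bool = False,
) -> SyllableTemplate:
    """Derive the next phrase's template from the current one.

    pitch: f0 glide scaled by a factor (direction random), everything else
    equal; timbre: noisiness and rolloff move, duration and f0 equal;
    stretch/squeeze: duration scaled up/down, contours equal; contrast: a
    fresh independent template. With ``clamp=True`` (used when chaining
    morphs through a song) out-of-range pitch or duration excursions are
    clipped to plausible bounds instead of raising.
    """
    params = params or MorphParams()
    rng = rng or np.random.default_rng()
    mode = MorphMode(mode)
    nyquist = sample_rate / 2.0

    if mode is MorphMode.CONTRAST:
        return random_template(rng)
    if mode is MorphMode.PITCH:
        factor = rng.uniform(*params.pitch_factor_range)
        if rng.random() < 0.5:
            factor = 1.0 / factor
        if clamp:
            new_max = t.f0_max_hz * factor
            if not _F0_CLAMP_HZ[0] <= new_max <= _F0_CLAMP_HZ[1]:
                factor = 1.0 / factor
        new = replace(
            t,
            f0_start_hz=t.f0_start_hz * factor,
            f0_end_hz=t.f0_end_hz * factor,
        )
        if new.f0_max_hz >= nyquist:
            raise InputError(
                f"pitch factor {factor:.2f} pushes f0 to {new.f0_max_hz:.0f} Hz, "
                f">= Nyquist {nyquist:.0f} Hz"
            )
        return new
    if mode is MorphMode.TIMBRE:
        delta = rng.uniform(*params.noisiness_delta_range)
        up = t.noisiness + delta <= 1.0 and (t.noisiness - delta < 0.0 or rng.random() < 0.5)
        noisiness = t.noisiness + delta if up else max(t.noisiness - delta, 0.0)
        roll_delta = rng.uniform(*params.rolloff_delta_db_range)
        rolloff = t.harmonic_rolloff_db + (roll_delta if rng.random() < 0.5 else -roll_delta)
        return replace(t, noisiness=float(np.clip(noisiness, 0.0, 1.0)),
                       harmonic_rolloff_db=float(np.clip(rolloff, 0.0, 24.0)))
    # stretch / squeeze
    factor = rng.uniform(*params.duration_factor_range)
    if mode is MorphMode.SQUEEZE:
        factor = 1.0 / factor
    new_dur = int(round(t.duration_ms * factor))
    if clamp:
        new_dur = int(np.clip(new_dur, *_DUR_CLAMP_MS))
    if new_dur < 1:
        raise InputError(f"duration factor {factor:.2f} collapses the syllable")
    return replace(t, duration_ms=new_dur)


def _render_song_from_templates(
    templates: list[SyllableTemplate],
    modes: list[MorphMode],
    spec: SongSpec,
    rng: np.random.Generator,
) -> tuple[AudioClip, SongGroundTruth]:
    sr = spec.sample_rate
    intervals: list[SyllableSegment] = []
    phrase_of: list[int] = []
    waves: list[tuple[int, np.ndarray]] = []  # (onset sample, waveform)
    pos_ms = spec.phrase_gap_ms  # lead-in silence so onsets are never at t=0
    for p, template in enumerate(templates):
        reps = int(rng.integers(spec.reps_range[0], spec.reps_range[1] + 1))
        for r in range(reps):
            onset = pos_ms
            offset = onset + template.duration_ms
            intervals.append(SyllableSegment(onset, offset))
            phrase_of.append(p)
            waves.append((int(round(onset * sr / 1000.0)), render_syllable(template, sr, rng)))
            pos_ms = offset + spec.minibreath_ms
        pos_ms = pos_ms - spec.minibreath_ms + spec.phrase_gap_ms
    total_ms = pos_ms
    samples = np.zeros(int(round(total_ms * sr / 1000.0)))
    for start, wave in waves:
        samples[start:start + len(wave)] += wave

    voiced_rms = np.sqrt(np.mean(np.concatenate([w ** 2 for _, w in waves])))
    noise_sigma = voiced_rms / 10 ** (spec.noise_snr_db / 20.0)
    samples = samples + rng.normal(0.0, noise_sigma, len(samples))
    peak = np.max(np.abs(samples))
    if peak > 0.99:
        samples *= 0.99 / peak

    truth = SongGroundTruth(
        syllable_intervals=intervals,
        phrase_of_syllable=phrase_of,
        transition_modes=modes,
        templates=templates,
        duration_ms=total_ms,
    )
    return AudioClip(samples=samples, sample_rate=sr), truth


def generate_song(spec: SongSpec) -> tuple[AudioClip, SongGroundTruth]:
    """Simulate a song bout whose phrase sequence is linked by morphs.

    The first phrase uses a random template; each subsequent phrase derives
    its template by applying a morph mode sampled from
    ``spec.mode_probabilities`` to the previous template. Fully determined
    by ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    mode_names = sorted(spec.mode_probabilities)
    probs = np.array([spec.mode_probabilities[m] for m in mode_names])
    templates = [random_template(rng)]
    modes: list[MorphMode] = []
    for _ in range(spec.n_phrases - 1):
        mode = MorphMode(mode_names[int(rng.choice(len(mode_names), p=probs))])
        modes.append(mode)
        templates.append(
            apply_morph(templates[-1], mode, spec.morph_params, rng,
                        sample_rate=spec.sample_rate, clamp=True)
        )
    return _render_song_from_templates(templates, modes, spec, rng)


def generate_null_song(spec: SongSpec) -> tuple[AudioClip, SongGroundTruth]:
    """Simulate a song with *independent* phrase templates (no morph linkage).

    Every transition is labelled contrast; adjacent phrases are no more
    similar than distant ones by construction, which makes this the type-I
    error fixture for the adjacent-vs-distant test.
    """
    rng = np.random.default_rng(spec.seed)
    templates = [random_template(rng) for _ in range(spec.n_phrases)]
    modes = [MorphMode.CONTRAST] * (spec.n_phrases - 1)
    return _render_song_from_templates(templates, modes, spec, rng)


def syllable_from_template(
    t: SyllableTemplate,
    sample_rate: int = DEFAULT_SAMPLE_RATE,
    rng: np.random.Generator | None = None,
    pad_ms: int = 50,
) -> Syllable:
    """Render a template and measure its feature contours directly.

    The syllable is rendered into a short silence-padded clip, features are
    extracted, and the contours on the known interval are returned — a
    convenience for tests and examples that need measured (not idealised)
    contours without running the segmenter.
    """
    sr = sample_rate
    wave = render_syllable(t, sr, rng)
    pad = np.zeros(int(round(pad_ms * sr / 1000.0)))
    clip = AudioClip(np.concatenate([pad, wave, pad]), sr)
    amp, freq, ent = feature_tracks(clip)
    seg = SyllableSegment(pad_ms, pad_ms + t.duration_ms)
    return Syllable(
        segment=seg,
        amp=amp.slice_ms(seg.onset_ms, seg.offset_ms),
        freq=freq.slice_ms(seg.onset_ms, seg.offset_ms),
        ent=ent.slice_ms(seg.onset_ms, seg.offset_ms),
    )


def write_song(
    outdir: str | Path,
    clip: AudioClip,
    truth: SongGroundTruth,
    spec: SongSpec,
    stem: str = "song",
) -> dict[str, Path]:
    """Write WAV + ground-truth CSV + a JSON echo of the generating spec."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "wav": outdir / f"{stem}.wav",
        "truth": outdir / f"{stem}_truth.csv",
        "spec": outdir / f"{stem}_spec.json",
    }
    save_audio(paths["wav"], clip)
    pd.DataFrame(
        {
            "onset_ms": [s.onset_ms for s in truth.syllable_intervals],
            "offset_ms": [s.offset_ms for s in truth.syllable_intervals],
            "phrase_index": truth.phrase_of_syllable,
            "transition_mode_into_phrase": [
                truth.transition_modes[p - 1].value if p > 0 else ""
                for p in truth.phrase_of_syllable
            ],
        }
    ).to_csv(paths["truth"], index=False)
    spec_dict = asdict(spec)
    spec_dict["morph_params"] = asdict(spec.morph_params)
    paths["spec"].write_text(json.dumps(spec_dict, indent=2, default=str))
    return paths
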