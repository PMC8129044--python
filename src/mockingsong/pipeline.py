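"""End-to-end orchestration: features -> segmentation -> phrasing -> stats -> modes.

A :class:`RunConfig` names either an input recording (plus optional phrase
annotations) or a simulation spec, along with every tunable parameter and
the RNG seed. :func:`run_analysis` executes the full analysis and writes a
report bundle of CSVs plus a plain-text log of all parameters, so any run
can be reproduced from its output directory alone.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import segment as seg
from .audio import AudioClip, load_audio
from .distance import PairDistance
from .errors import InputError
from .features import feature_tracks, write_feature_csv
from .modes import calibrate_thresholds, classify_transition, mode_frequency_table
from .phrasing import (
    DEFAULT_PHRASE_GAP_MS,
    assign_syllables_to_phrases,
    group_into_phrases,
    phrases_to_frame,
    read_annotations,
)
from .simulate import SongSpec, generate_song, write_song
from .stats import compare_song, comparisons_to_frame, results_to_frame, test_features

__all__ = ["RunConfig", "run_analysis", "run_simulate"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Parameters of one analysis run; exactly one input source must be set."""

    audio_path: str | None = None
    annotations_path: str | None = None
    simulation: SongSpec | None = None
    amp_threshold: float = seg.DEFAULT_AMP_THRESHOLD
    ent_threshold: float = seg.DEFAULT_ENT_THRESHOLD
    auto_thresholds: bool = False
    min_dur_ms: int = seg.DEFAULT_MIN_DUR_MS
    min_gap_ms: int = seg.DEFAULT_MIN_GAP_MS
    phrase_gap_ms: int = DEFAULT_PHRASE_GAP_MS
    k_distant: int = 10
    exclusion: int = 10
    n_tests_for_correction: int = 4
    seed: int = 0
    outdir: str = "mockingsong_out"
    bird: str = ""
    write_features: bool = False

    def __post_init__(self) -> None:
        if (self.audio_path is None) == (self.simulation is None):
            raise InputError("exactly one of audio_path or simulation must be set")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = raw.pop("simulation", None)
        if sim is not None:
            sim = SongSpec(**sim)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise InputError(f"unknown config keys: {sorted(unknown)}")
        return cls(simulation=sim, **raw)


def run_analysis(config: RunConfig) -> dict[str, Path]:
    """Run the full adjacent-vs-distant analysis and write the report bundle.

    Returns the paths written: segments, phrases, distance table, the
    per-feature statistics table, the mode-frequency table, transition
    labels, and a run log naming every parameter and the seed.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    if config.simulation is not None:
        clip, _truth = generate_song(config.simulation)
        source = f"simulated (seed={config.simulation.seed})"
    else:
        clip = load_audio(config.audio_path)
        source = str(config.audio_path)

    amp, freq, ent = feature_tracks(clip)
    if config.auto_thresholds:
        amp_th, ent_th = seg.auto_thresholds(amp, ent)
    else:
        amp_th, ent_th = config.amp_threshold, config.ent_threshold
    segments = seg.segment_syllables(
        amp, ent, amp_th, ent_th, config.min_dur_ms, config.min_gap_ms
    )
    if not segments:
        raise InputError(f"no syllables segmented in {source}; check thresholds")
    syllables = seg.extract_syllables(segments, amp, freq, ent)

    if config.annotations_path:
        phrases = assign_syllables_to_phrases(syllables, read_annotations(config.annotations_path))
    else:
        phrases = group_into_phrases(syllables, config.phrase_gap_ms)

    comparisons = compare_song(
        phrases, k=config.k_distant, exclusion=config.exclusion, seed=config.seed
    )
    if not comparisons:
        raise InputError("no focal phrase had enough eligible distant phrases")
    results = test_features(comparisons, n_tests_for_correction=config.n_tests_for_correction)

    distant: list[PairDistance] = [d for c in comparisons for d in c.distant]
    thresholds = calibrate_thresholds(distant)
    labels = []
    for c in comparisons:
        pre = phrases[c.focal_index].mean_syllable_duration_ms
        post = phrases[c.focal_index + 1].mean_syllable_duration_ms
        labels.append((c.focal_index, classify_transition(c.adjacent, (pre, post), thresholds)))

    paths: dict[str, Path] = {}
    if config.write_features:
        paths["features"] = outdir / "features.csv"
        write_feature_csv(paths["features"], (amp, freq, ent))
    paths["segments"] = outdir / "segments.csv"
    seg.write_segments_csv(paths["segments"], segments)
    paths["phrases"] = outdir / "phrases.csv"
    phrases_to_frame(phrases).to_csv(paths["phrases"], index=False)
    paths["distances"] = outdir / "distances.csv"
    comparisons_to_frame(comparisons).to_csv(paths["distances"], index=False)
    paths["stats"] = outdir / "stats.csv"
    results_to_frame(results, bird=config.bird).to_csv(paths["stats"], index=False)
    paths["modes"] = outdir / "mode_frequencies.csv"
    mode_frequency_table([m for _, m in labels]).to_csv(paths["modes"], index=False)
    paths["transitions"] = outdir / "transition_labels.csv"
    _write_transition_labels(paths["transitions"], comparisons, labels)
    paths["log"] = outdir / "run_log.txt"
    _write_log(paths["log"], config, source, amp_th, ent_th, len(segments), len(phrases))
    return paths


def _write_transition_labels(path: Path, comparisons, labels) -> None:
    import pandas as pd

    by_focal = {c.focal_index: c for c in comparisons}
    rows = []
    for focal, mode in labels:
        d = by_focal[focal].adjacent
        rows.append(
            {
                "phrase_index": focal,
                "mode": mode.value,
                "amp_dist": d.amp_dist,
                "freq_dist": d.freq_dist,
                "ent_dist": d.ent_dist,
                "dur_ratio": d.dur_ratio,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def _write_log(path: Path, config: RunConfig, source: str,
               amp_th: float, ent_th: float, n_segments: int, n_phrases: int) -> None:
    lines = [
        f"source: {source}",
        f"seed: {config.seed}",
        f"amp_threshold: {amp_th}",
        f"ent_threshold: {ent_th}",
        f"min_dur_ms: {config.min_dur_ms}",
        f"min_gap_ms: {config.min_gap_ms}",
        f"phrase_gap_ms: {config.phrase_gap_ms}",
        f"k_distant: {config.k_distant}",
        f"exclusion: {config.exclusion}",
        f"n_tests_for_correction: {config.n_tests_for_correction}",
        f"n_segments: {n_segments}",
        f"n_phrases: {n_phrases}",
    ]
    path.write_text("\n".join(lines) + "\n")


def run_simulate(spec: SongSpec, outdir: str | Path, stem: str = "song") -> dict[str, Path]:
    """Generate a synthetic song and write WAV + ground truth + spec echo."""
    clip, truth = generate_song(spec)
    return write_song(outdir, clip, truth, spec, stem=stem)
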