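"""Segment a simulated song bout into syllables and group them into phrases.

Generates a 12-phrase bout with known ground truth, runs the dual-threshold
segmenter (louder than the amplitude threshold AND more tone-like than the
entropy threshold), groups syllables by the inter-syllable gap, and compares
against the ground truth.
"""

from mockingsong import (
    SongSpec,
    extract_syllables,
    feature_tracks,
    generate_song,
    group_into_phrases,
    segment_syllables,
)

spec = SongSpec(n_phrases=12, seed=42)
clip, truth = generate_song(spec)
print(f"simulated bout: {clip.duration_ms/1000:.1f} s, "
      f"{truth.n_syllables} syllables in {truth.n_phrases} phrases")

amp, freq, ent = feature_tracks(clip)
segments = segment_syllables(amp, ent)  # amp > 0.1 AND entropy < -0.5
syllables = extract_syllables(segments, amp, freq, ent)
phrases = group_into_phrases(syllables, phrase_gap_ms=250)

print(f"segmenter found {len(segments)} syllables "
      f"({truth.n_syllables} true); first three intervals (ms):")
for seg, true in zip(segments[:3], truth.syllable_intervals[:3]):
    print(f"  detected [{seg.onset_ms}, {seg.offset_ms})  true [{true.onset_ms}, {true.offset_ms})")
print(f"gap heuristic grouped them into {len(phrases)} phrases ({truth.n_phrases} true)")
print("phrase sizes:", [len(p) for p in phrases])
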