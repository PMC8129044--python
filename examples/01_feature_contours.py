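"""Extract the three per-millisecond feature contours from a rendered syllable.

Renders a 150 ms two-note syllable (2 kHz fundamental gliding to 2.6 kHz,
20% noise mix), embeds it in silence, and prints what each contour measures
at the syllable's midpoint.
"""

import numpy as np

from mockingsong import AudioClip, SyllableTemplate, feature_tracks, render_syllable

template = SyllableTemplate(
    duration_ms=150, f0_start_hz=2000.0, f0_end_hz=2600.0,
    n_harmonics=3, noisiness=0.2, n_notes=2,
)
wave = render_syllable(template, sample_rate=22050, rng=np.random.default_rng(0))
pad = np.zeros(22050 // 10)  # 100 ms of silence either side
clip = AudioClip(np.concatenate([pad, wave, pad]), 22050)

amp, freq, ent = feature_tracks(clip)
mid = 100 + template.duration_ms // 2  # ms index of the syllable midpoint

print(f"track length: {len(amp)} ms (one value per millisecond)")
print(f"normalised amplitude at midpoint: {amp.values[mid]:.2f}  (0 = silence, 1 = window peak)")
print(f"mean frequency at midpoint:       {freq.values[mid]:.0f} Hz (power-weighted centroid; "
      "above f0 because harmonics carry power)")
print(f"Wiener entropy at midpoint:       {ent.values[mid]:.2f}  (log10 spectral flatness; "
      "0 = white noise, very negative = pure tone)")
print(f"background entropy (in silence):  {ent.values[20]:.2f}")
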