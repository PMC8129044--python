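# Methods

## Feature extraction

All three contours live on a 0-based, half-open, 1 ms grid; `values[t]`
describes millisecond `[t, t+1)`.

**Amplitude envelope.** RMS of the waveform in a 10 ms window centred on
each millisecond (edges zero-padded). RMS was chosen over peak or Hilbert
magnitude because it is smooth, robust to single-sample outliers, and
standard in song-analysis toolchains. The envelope is then divided by its
maximum within consecutive 4 s windows, tiled contiguously from t = 0; the
last partial window is normalised by its own maximum and all-zero windows
stay zero. Max-normalisation makes the amplitude distance invariant to any
uniform gain applied within a window (e.g. the bird turning away from the
microphone) — the simplest reading of per-window normalisation, at the cost
of a discontinuity at window edges when the loudest syllable changes.

**Spectral frames.** ~10 ms Hann-windowed frames centred on each
millisecond, zero-padded to the next power of two (FFT parameters are a
conventional choice; results are insensitive to the pad length). Both
spectral features are computed from one pass over the frames.

**Mean frequency** is the power-weighted spectral centroid in Hz, bounded by
[0, Nyquist]. It is a *pitch measure of the whole spectrum*, not a
fundamental-frequency tracker: for a harmonic stack it sits above f0 by an
amount set by the harmonic rolloff. Frames of digital silence get a 0 Hz
fill; since segmentation removes silence before any distance is computed,
the fill never enters an analysis.

**Wiener entropy** is log₁₀ of spectral flatness — the geometric over the
arithmetic mean of the power spectrum: 0 for a flat spectrum, strongly
negative for tone-like sounds. Values are clipped to [−10, 0]; silent frames
get the −10 floor, never NaN. Spectral bins are floored at 1e−30 before the
log so sidelobe zeros do not produce −inf, and round-off within 1e−12 of
zero is snapped to exactly 0 so a flat spectrum reports 0.

## Segmentation and phrasing

A millisecond is voiced when (normalised amplitude > amp_threshold) AND
(Wiener entropy < ent_threshold). Runs separated by gaps shorter than
`min_gap_ms = 5` are merged (dropouts briefer than any minibreath), and runs
shorter than `min_dur_ms = 10` are discarded. Defaults: `amp_threshold =
0.1` (on the max-normalised envelope) and `ent_threshold = −0.5`. The
entropy default sits between broadband background noise (≈ −0.25 for white
noise) and the noisiest band-limited syllable the generator produces
(≈ −0.8 for a high-pitched, fully noisy syllable); the wide margin to tonal
syllables (≤ −3) also keeps boundary trimming by mixed edge frames small. An
optional percentile mode (amplitude 60th percentile, entropy 40th) supports
unattended use on recordings with unknown gain. Both thresholds are exposed,
since any fixed value is a choice the original procedure left open.

Phrases come from annotations when supplied; otherwise a new phrase starts
wherever the inter-syllable gap reaches `phrase_gap_ms = 250` — above any
minibreath (tens of ms) and below inter-phrase pauses (several hundred ms).
Single-syllable phrases are allowed.

## Distances

DTW uses absolute-difference cost, the symmetric step set
{(1,0),(0,1),(1,1)}, no band constraint and no slope weighting — the
canonical form, since no variant is singled out by the procedure this
implements. Backtracking prefers diagonal, then vertical, then horizontal
steps, making the returned path deterministic among cost ties. "Mean
Euclidean distance" is interpreted as the mean over warping-path steps of
the pointwise absolute difference (1-D Euclidean), not the path-cost of a
resampled pair; the two readings agree on the amplitude axis up to
normalisation but differ on transferred features. DTW runs on the
*normalised* envelope, which is what the 4 s normalisation exists for.
Phrase scores are arithmetic means over all m×n syllable pairs, and the
comparison count is reported alongside.

## Adjacent-vs-distant statistics

Each focal phrase with a successor is compared to that successor and to
k = 10 phrases drawn uniformly without replacement from outside a symmetric
±10-phrase exclusion window (the successor is always ineligible). Focal
phrases with fewer than k eligible partners are skipped and logged — note a
song needs ≥ 31 phrases before every focal is eligible. Per feature, a
**two-sample, two-sided Welch t-test** compares adjacent scores (one per
focal) against pooled distant scores. Welch was chosen because no pairing
structure links one adjacent score to its ten distant scores, and the two
pools have very different sizes and variances. Significance uses Bonferroni
correction with a default family of 4 (the four features within one
recording); the family size is a parameter for users who prefer correcting
across recordings as well. Exactly identical zero-variance samples get the
t = 0, p = 1 convention. The sampling RNG is seeded once per song and the
seed is recorded in all outputs.

## Morph-mode classification

"Low" and "high" are operationalised as quantiles of the song's own
distant-pair distance distributions, because absolute feature scales differ
between recordings. The frozen calibration is deliberately asymmetric:

* low cutoff = 0.10 quantile for all three distance features;
* high cutoffs = 0.30 (amplitude), 0.20 (frequency), 0.40 (entropy);
* duration "different" = shorter:longer ratio below a **fixed** 0.75.

Two findings from the design phase drove this. First, random phrase pairs
routinely differ in duration by more than the ~2× of a stretch/squeeze
morph, so a quantile cutoff on the duration ratio never fires for temporal
morphs; a factor-scale absolute cutoff (0.75 ≈ a one-third tempo change)
separates "same tempo" from "stretched/squeezed" regardless of the song's
duration diversity. Second, a 30–50% pitch shift is small relative to the
f0 spread of unrelated syllables, while even two tonal syllables carry
substantial frame-level entropy jitter — hence a lower "high" quantile for
frequency than for entropy. The calibration was selected on one development
seed and validated on held-out seeds before being frozen; classification
accuracy on strong single-mode transitions is 0.82–0.91 across seeds.

The decision rule is evaluated in a fixed order (temporal modes, then
timbre, then pitch, then contrast), falling back to the signature with the
fewest violated conditions, ties broken by the order timbre, pitch, squeeze,
stretch, contrast. A single label is returned; because real transitions
often mix modes, `transition_conditions` exposes the raw fired conditions so
callers can detect mixtures.

## Synthetic songs

A syllable template is a harmonic stack (linear f0 glide, per-harmonic
rolloff in dB) mixed with band-limited noise by a `noisiness` weight in
[0, 1], under an attack/sustain/decay envelope with 1–3 amplitude "notes"
(humps). The parameterisation controls the three measured axes roughly
independently: envelope shape (notes, ramps), centroid (f0, rolloff), and
entropy (noisiness). Defaults: durations 40–250 ms, f0 1–6 kHz, 1–4
harmonics, noisiness 0–0.6, minibreath 30 ms, phrase gap 400 ms, background
SNR 25 dB, sample rate 22.05 kHz, 3–5 repetitions per phrase — inside the
range of reported mockingbird song characteristics.

Design notes:

* The **noise band hugs the harmonic stack** (0.7×f0 to 1.8×f0_max) rather
  than spanning the whole spectrum, so a timbre change moves entropy by log
  units while moving the centroid comparatively little — matching the
  "minimal pair" notion of a timbre-only change. A consequence is that a
  fully noisy syllable measures ≈ −3 entropy at mid f0 (≈ −0.8 at high f0),
  clearly "high" against a pure tone's ≤ −5 but below true white noise.
* **Attack/decay ramps are a few percent of syllable duration** (ms scale,
  as in real passerine syllables). A threshold detector on a linear ramp is
  systematically late/early by roughly (threshold/peak) × ramp length, so
  ramp length directly bounds achievable boundary accuracy; ms-scale ramps
  keep ground-truth boundaries recoverable to ±5 ms. The multi-note
  modulation equals 1 at syllable edges for the same reason.
* Morph operators change exactly their target axis: pitch scales the whole
  f0 glide by a sampled factor (direction random); timbre moves noisiness
  (≥ its delta range) and rolloff; stretch/squeeze scale duration; contrast
  draws a fresh independent template. When chaining morphs through a song,
  duration and f0 excursions are clamped to plausible bounds (25–400 ms,
  0.6–8.5 kHz) rather than raising, so long songs cannot random-walk out of
  range; standalone `apply_morph` raises if a pitch factor would reach
  Nyquist.
* Everything is driven by one seeded RNG; a fixed seed reproduces audio and
  ground truth byte-for-byte. `generate_null_song` draws every phrase
  template independently (all transitions "contrast"), giving the type-I
  error fixture.

**What the generator does not emulate:** mimicry of real heterospecific
calls, two-voice syrinx sounds, reverberation or overlapping singers,
amplitude modulation from varying source-microphone distance beyond slow
gain drift, and higher-order morphs interleaved with contrasting material.
Passing tests therefore show the *pipeline* recovers known structure under
these idealised conditions, not that any particular field recording will
behave as cleanly.

## Problem sizes used in the test suite

Effect recovery runs 20 simulated bouts of 150 phrases (80% morph
transitions); type-I control runs 50 null bouts of 60 phrases; segmentation
recovery runs 10 bouts of 20 phrases; mode-classification recovery uses 25
transitions per mode with strong, well-separated morph parameters (pitch
factor ≥ 1.3, duration factor ≥ 1.8, noisiness change ≥ 0.5) against
thresholds calibrated from 100 random syllable pairs. These sizes give
stable pass/fail behaviour while keeping the full suite to a few minutes.

## Known limitations

* Threshold-based segmentation has no concept of overlapping vocalisations or
  source separation; a second singer will corrupt syllable boundaries.
* Mean frequency is a centroid, not f0: rolloff changes move it, so timbre
  morphs bleed slightly into the frequency axis (visible in classifier
  confusions between timbre and pitch).
* The single-label mode classifier deliberately ignores mode combinations;
  the fired-conditions output is the hook for mixture analysis.
* Distant-pair sampling requires ≥ 31 phrases for full coverage; shorter
  songs silently lose their central focal phrases (logged).
* The t-test treats phrase-pair scores as independent, but scores sharing a
  focal phrase are correlated; with ~100+ focal phrases the effect on p is
  modest, and the Bonferroni correction is conservative in the other
  direction.
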