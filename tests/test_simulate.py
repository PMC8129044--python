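import numpy as np
import pytest

from mockingsong import (
    InputError,
    MorphMode,
    MorphParams,
    SongSpec,
    SyllableTemplate,
    apply_morph,
    generate_null_song,
    generate_song,
    random_template,
    render_syllable,
    syllable_from_template,
)
from mockingsong.distance import syllable_distance

SMALL = dict(n_phrases=10, reps_range=(4, 4), seed=7)


class TestRenderSyllable:
    def test_sample_count_arithmetic(self):
        t = SyllableTemplate(duration_ms=80)
        assert len(render_syllable(t, 44100, np.random.default_rng(0))) == 3528

    def test_pure_tone_template_measures_its_f0(self):
        t = SyllableTemplate(duration_ms=120, f0_start_hz=2000, f0_end_hz=2000,
                            n_harmonics=1, noisiness=0.0)
        syl = syllable_from_template(t, rng=np.random.default_rng(0))
        assert np.median(syl.freq) == pytest.approx(2000, abs=100)

    def test_fully_noisy_template_has_high_entropy(self):
        tonal = syllable_from_template(
            SyllableTemplate(noisiness=0.0), rng=np.random.default_rng(1))
        noisy = syllable_from_template(
            SyllableTemplate(noisiness=1.0), rng=np.random.default_rng(1))
        # band-limited noise sits well above a pure tone but below white noise
        assert noisy.ent.mean() > tonal.ent.mean() + 1.5
        assert noisy.ent.mean() <= -2

    def test_f0_above_nyquist_rejected(self):
        with pytest.raises(InputError):
            render_syllable(SyllableTemplate(f0_start_hz=12000), 22050)

    def test_peak_bounded(self):
        wave = render_syllable(SyllableTemplate(), 22050, np.random.default_rng(2))
        assert np.max(np.abs(wave)) <= 1.0


class TestApplyMorph:
    def test_stretch_scales_duration_only(self):
        t = SyllableTemplate(duration_ms=100, f0_start_hz=1000, f0_end_hz=1200)
        params = MorphParams(duration_factor_range=(2.0, 2.0))
        out = apply_morph(t, MorphMode.STRETCH, params, np.random.default_rng(0))
        assert out.duration_ms == 200
        assert (out.f0_start_hz, out.f0_end_hz) == (1000, 1200)

    def test_squeeze_shrinks_duration(self):
        t = SyllableTemplate(duration_ms=100)
        params = MorphParams(duration_factor_range=(2.0, 2.0))
        out = apply_morph(t, MorphMode.SQUEEZE, params, np.random.default_rng(0))
        assert out.duration_ms == 50

    def test_pitch_scales_whole_glide(self):
        t = SyllableTemplate(duration_ms=100, f0_start_hz=1000, f0_end_hz=1200)
        params = MorphParams(pitch_factor_range=(1.5, 1.5))
        out = apply_morph(t, MorphMode.PITCH, params, np.random.default_rng(3))
        factor = out.f0_start_hz / t.f0_start_hz
        assert factor == pytest.approx(1.5) or factor == pytest.approx(1 / 1.5)
        assert out.f0_end_hz / t.f0_end_hz == pytest.approx(factor)
        assert out.duration_ms == 100

    def test_pitch_factor_to_nyquist_rejected(self):
        t = SyllableTemplate(f0_start_hz=8000, f0_end_hz=8000)
        params = MorphParams(pitch_factor_range=(1.5, 1.5))
        rng = np.random.default_rng(0)
        with pytest.raises(InputError):
            # force the upward direction by retrying until it would go up
            for _ in range(20):
                apply_morph(t, MorphMode.PITCH, params, rng)

    def test_timbre_changes_entropy_but_not_tempo(self):
        rng = np.random.default_rng(4)
        t = SyllableTemplate(duration_ms=100, noisiness=0.1)
        out = apply_morph(t, MorphMode.TIMBRE, MorphParams(noisiness_delta_range=(0.6, 0.6)), rng)
        assert out.duration_ms == t.duration_ms
        assert (out.f0_start_hz, out.f0_end_hz) == (t.f0_start_hz, t.f0_end_hz)
        sa = syllable_from_template(t, rng=rng)
        sb = syllable_from_template(out, rng=rng)
        d = syllable_distance(sa, sb)
        assert d.dur_ratio == pytest.approx(1.0, abs=0.02)
        assert d.ent_dist > 1.0  # entropy moved far
        assert d.freq_dist / np.mean(sa.freq) < 0.25  # centroid roughly conserved

    def test_contrast_draws_fresh_template(self):
        t = SyllableTemplate()
        out = apply_morph(t, MorphMode.CONTRAST, rng=np.random.default_rng(5))
        assert out != t


class TestMorphLocality:
    """Each morph changes its target axis and conserves the others (measured)."""

    def test_pitch_morph_conserves_duration(self):
        rng = np.random.default_rng(6)
        t = random_template(rng)
        out = apply_morph(t, MorphMode.PITCH, rng=rng)
        assert abs(out.duration_ms - t.duration_ms) <= 0.02 * t.duration_ms

    def test_stretch_conserves_f0_contour_endpoints(self):
        rng = np.random.default_rng(7)
        t = random_template(rng)
        out = apply_morph(t, MorphMode.STRETCH, rng=rng)
        assert out.f0_start_hz == t.f0_start_hz and out.f0_end_hz == t.f0_end_hz


class TestGenerateSong:
    def test_fixed_seed_reproducible(self):
        spec = SongSpec(**SMALL)
        clip1, truth1 = generate_song(spec)
        clip2, truth2 = generate_song(spec)
        np.testing.assert_array_equal(clip1.samples, clip2.samples)
        assert truth1.syllable_intervals == truth2.syllable_intervals
        assert truth1.transition_modes == truth2.transition_modes

    def test_counting_contract(self):
        _clip, truth = generate_song(SongSpec(**SMALL))
        assert truth.n_syllables == 40  # 10 phrases x 4 reps
        assert len(truth.transition_modes) == 9
        assert truth.n_phrases == 10

    def test_ground_truth_intervals_sorted_disjoint(self):
        _clip, truth = generate_song(SongSpec(n_phrases=12, seed=3))
        ivs = truth.syllable_intervals
        assert all(a.offset_ms <= b.onset_ms for a, b in zip(ivs, ivs[1:]))

    def test_audio_duration_matches_bookkeeping(self):
        spec = SongSpec(**SMALL)
        clip, truth = generate_song(spec)
        # rendered span = ground-truth span + trailing phrase gap (the lead-in
        # gap is part of duration_ms bookkeeping)
        assert truth.duration_ms == truth.syllable_intervals[-1].offset_ms + spec.phrase_gap_ms
        assert len(clip.samples) == int(round(truth.duration_ms * spec.sample_rate / 1000))

    def test_invalid_mode_probabilities_rejected(self):
        with pytest.raises(InputError, match="sum to 1"):
            SongSpec(mode_probabilities={"timbre": 0.5, "contrast": 0.2})
        with pytest.raises(InputError, match="unknown"):
            SongSpec(mode_probabilities={"vibrato": 1.0})

    def test_reps_range_validated(self):
        with pytest.raises(InputError):
            SongSpec(reps_range=(0, 5))


class TestGenerateNullSong:
    def test_deterministic(self):
        spec = SongSpec(**SMALL)
        clip1, _ = generate_null_song(spec)
        clip2, _ = generate_null_song(spec)
        np.testing.assert_array_equal(clip1.samples, clip2.samples)

    def test_all_transitions_contrast(self):
        _clip, truth = generate_null_song(SongSpec(**SMALL))
        assert all(m == MorphMode.CONTRAST for m in truth.transition_modes)
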