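"""Spectrogram, segmentation and feature-extraction tests."""

import numpy as np
import pytest

import usvkit as uk
from usvkit.spectro import (
    SpectrogramParams,
    TooFewFramesError,
    extract_features,
    wiener_entropy,
)


def _tone(freq_hz, dur_s, sr, amp=0.3):
    t = np.arange(int(dur_s * sr)) / sr
    return amp * np.sin(2 * np.pi * freq_hz * t)


def test_pure_tone_calibration_440hz():
    """The 440 Hz tuning-fork check: peak within one bin of 440 Hz."""
    sr = 48_000.0
    params = SpectrogramParams(sample_rate=sr)
    spec = uk.compute_spectrogram(_tone(440, 0.2, sr), params)
    mean_db = spec.db.mean(axis=0)
    peak_hz = spec.freqs_hz[np.argmax(mean_db)]
    bin_hz = sr / params.fft_length
    assert abs(peak_hz - 440.0) <= bin_hz


def test_70khz_tone_lands_in_bin_143():
    """Closed-form bin arithmetic: round(70000 * 512 / 250000) = 143."""
    sr = 250_000.0
    spec = uk.compute_spectrogram(_tone(70_000, 0.05, sr), SpectrogramParams())
    peak_bin = int(np.argmax(spec.db.mean(axis=0)))
    assert peak_bin == round(70_000 * 512 / 250_000) == 143


def test_full_scale_sine_reads_near_zero_db():
    sr = 250_000.0
    spec = uk.compute_spectrogram(_tone(70_000, 0.05, sr, amp=1.0), SpectrogramParams())
    assert abs(spec.db.max()) < 1.0


def test_all_zero_signal_sits_at_floor():
    params = SpectrogramParams()
    spec = uk.compute_spectrogram(np.zeros(5000), params)
    assert np.all(spec.db == params.noise_floor_db)
    assert uk.segment_syllables(spec) == []


def test_empty_and_short_signals_rejected():
    with pytest.raises(ValueError, match="empty"):
        uk.compute_spectrogram(np.array([]))
    with pytest.raises(ValueError, match="shorter"):
        uk.compute_spectrogram(np.zeros(100))


def test_frame_spacing_follows_overlap():
    sr = 250_000.0
    params = SpectrogramParams(sample_rate=sr, overlap_fraction=0.5)
    spec = uk.compute_spectrogram(np.zeros(10_000), params)
    np.testing.assert_allclose(np.diff(spec.times), 256 / sr)


def test_params_validation():
    with pytest.raises(ValueError, match="power of two"):
        SpectrogramParams(fft_length=500)
    with pytest.raises(ValueError, match="overlap"):
        SpectrogramParams(overlap_fraction=1.0)


def _two_tone_signal(sr, gap_s, dur_s=0.03):
    tone = _tone(70_000, dur_s, sr)
    gap = np.zeros(int(gap_s * sr))
    return np.concatenate([np.zeros(int(0.02 * sr)), tone, gap, tone,
                           np.zeros(int(0.02 * sr))])


def test_segmentation_splits_on_long_gap():
    sr = 250_000.0
    sig = _two_tone_signal(sr, gap_s=0.05)
    spec = uk.compute_spectrogram(sig, SpectrogramParams())
    assert len(uk.segment_syllables(spec, gap_ms=10)) == 2


def test_segmentation_merges_short_gap():
    sr = 250_000.0
    sig = _two_tone_signal(sr, gap_s=0.005)
    spec = uk.compute_spectrogram(sig, SpectrogramParams())
    assert len(uk.segment_syllables(spec, gap_ms=10)) == 1


def test_min_duration_filter():
    sr = 250_000.0
    sig = _two_tone_signal(sr, gap_s=0.05, dur_s=0.002)  # 2 ms blips
    spec = uk.compute_spectrogram(sig, SpectrogramParams())
    assert uk.segment_syllables(spec, min_dur_ms=5) == []
    assert len(uk.segment_syllables(spec, min_dur_ms=1)) == 2


def test_entropy_extremes():
    """Single-bin spectrum -> near 0; flat spectrum -> exactly 1."""
    line = np.full(257, 1e-9)
    line[100] = 1.0
    assert wiener_entropy(line) < 0.01
    assert wiener_entropy(np.full(257, 0.5)) == pytest.approx(1.0)


def test_pure_tone_features():
    """Tonal syllable: all four peak frequencies at the tone, entropy < 0.3."""
    sr = 250_000.0
    sig = np.concatenate([np.zeros(2048), _tone(70_000, 0.03, sr), np.zeros(2048)])
    spec = uk.compute_spectrogram(sig, SpectrogramParams())
    (syl,) = uk.segment_syllables(spec)
    f = extract_features(syl)
    bin_khz = sr / 512 / 1000
    for pos in ("start", "end", "center", "max"):
        assert f[f"pF{pos}"] == pytest.approx(70.0, abs=1.5 * bin_khz)
        assert f[f"minF{pos}"] <= f[f"pF{pos}"] <= f[f"maxF{pos}"]
        assert f[f"band{pos}"] == pytest.approx(f[f"maxF{pos}"] - f[f"minF{pos}"])
        assert f[f"ent{pos}"] < 0.3
    assert f["duration"] == pytest.approx(0.03, abs=0.005)


def test_noise_syllable_has_high_entropy(rng):
    """Broadband noise burst: entropy > 0.4."""
    sr = 250_000.0
    burst = 0.2 * rng.standard_normal(int(0.03 * sr))
    sig = np.concatenate([np.zeros(2048), burst, np.zeros(2048)])
    spec = uk.compute_spectrogram(sig, SpectrogramParams(noise_floor_db=-60.0))
    (syl,) = uk.segment_syllables(spec)
    f = extract_features(syl)
    assert f["entmax"] > 0.4


def test_chirp_start_end_frequencies():
    """Linear 60 -> 80 kHz chirp: pFstart ~ 60, pFend ~ 80, monotone contour."""
    sr = 250_000.0
    n = int(0.04 * sr)
    t = np.arange(n) / sr
    f_inst = 60_000 + (80_000 - 60_000) * t / t[-1]
    sig = 0.3 * np.sin(2 * np.pi * np.cumsum(f_inst) / sr)
    sig = np.concatenate([np.zeros(2048), sig, np.zeros(2048)])
    spec = uk.compute_spectrogram(sig, SpectrogramParams())
    (syl,) = uk.segment_syllables(spec)
    f = extract_features(syl)
    assert f["pFstart"] == pytest.approx(60.0, abs=2.0)
    assert f["pFend"] == pytest.approx(80.0, abs=2.0)
    contour = syl.peak_contour_khz
    assert np.all(np.diff(contour) > -1.0)
    assert uk.classify_contour(contour) is uk.SyllableType.FREQUENCY_UPSWEEP


def test_gain_invariance_except_amplitude():
    """A uniform gain shifts only the amplitude features, by the gain in dB."""
    sr = 250_000.0
    base = np.concatenate([np.zeros(2048), _tone(70_000, 0.03, sr), np.zeros(2048)])
    gain_db = -12.0
    scaled = base * 10 ** (gain_db / 20)
    feats = []
    for sig in (base, scaled):
        spec = uk.compute_spectrogram(sig, SpectrogramParams())
        (syl,) = uk.segment_syllables(spec)
        feats.append(extract_features(syl))
    a, b = feats
    for key, val in a.items():
        if key.startswith("pAMP"):
            assert b[key] - val == pytest.approx(gain_db, abs=0.2)
        elif key.startswith(("ent",)):
            assert b[key] == pytest.approx(val, abs=0.02)
        else:
            assert b[key] == pytest.approx(val, abs=1e-6)


def test_too_few_frames_flagged():
    sr = 250_000.0
    sig = np.concatenate([np.zeros(2048), _tone(70_000, 0.0015, sr), np.zeros(2048)])
    spec = uk.compute_spectrogram(sig, SpectrogramParams())
    syls = uk.segment_syllables(spec, min_dur_ms=1)
    if syls and syls[0].n_frames < 3:
        with pytest.raises(TooFewFramesError):
            extract_features(syls[0])
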