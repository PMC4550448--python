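"""Waveform synthesis and WAV I/O for synthetic USV sequences.

Syllables are rendered as frequency-modulated tones: the instantaneous
frequency follows the syllable's contour (linear interpolation for sweeps
and U-shapes, zero-order hold for frequency-step calls, so a step is a true
instantaneous discontinuity with no time gap), the phase is the integral of
the instantaneous frequency, and the peak amplitude is set in dB re full
scale.  Tonality maps inversely to an additive broadband noise component
during the syllable; a very quiet background noise floor fills the silences.
Output is float in [-1, 1] or 16-bit PCM WAV.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.io import wavfile

from .simulate import SyntheticIndividual

__all__ = ["render_waveform", "write_wav", "read_wav"]

_EDGE_RAMP_S = 0.002
_BACKGROUND_DB = -95.0


def render_waveform(
    ind: SyntheticIndividual,
    sample_rate: float = 250_000.0,
    pad_s: float = 0.05,
    noise_seed: int | None = None,
    start_at_zero: bool = True,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Render a male's syllable sequence to audio with ground-truth timing.

    Parameters
    ----------
    ind
        Synthetic individual; an empty syllable list yields background noise
        of length ``2 * pad_s``.
    sample_rate
        Must exceed twice the highest contour frequency (Nyquist).
    pad_s
        Silence before the first and after the last syllable.
    noise_seed
        Seed of the additive noise; defaults to the male's feature seed.
    start_at_zero
        If True (default) the sequence is shifted so the first syllable
        starts at ``pad_s`` (latencies of many minutes would otherwise
        render minutes of silence).

    Returns
    -------
    (signal, truth)
        Float signal in [-1, 1] and a ground-truth table with one row per
        syllable: onset/offset (s, in signal time), type and peak amplitude.
    """
    syls = ind.syllables
    f_max = max((float(s.contour_khz.max()) for s in syls), default=0.0) * 1000.0
    if sample_rate < 2.0 * f_max:
        raise ValueError(
            f"sample_rate {sample_rate:g} Hz violates Nyquist for contour "
            f"maximum {f_max:g} Hz"
        )
    rng = np.random.default_rng(
        ind.feature_seed if noise_seed is None else noise_seed
    )
    if syls:
        t0 = (syls[0].t_start if start_at_zero else 0.0) - pad_s
        t_end = syls[-1].t_start + syls[-1].duration_s - t0 + pad_s
    else:
        t0, t_end = 0.0, 2.0 * pad_s
    n = int(np.ceil(t_end * sample_rate))
    sig = 10.0 ** (_BACKGROUND_DB / 20.0) * rng.standard_normal(n)

    truth_rows = []
    for s in syls:
        onset = s.t_start - t0
        i0 = int(round(onset * sample_rate))
        m = int(round(s.duration_s * sample_rate))
        if m < 8 or i0 + m > n:
            continue
        tt = np.arange(m) / sample_rate
        if s.interp == "previous":
            idx = np.searchsorted(s.contour_times_s, tt, side="right") - 1
            f_inst = s.contour_khz[np.clip(idx, 0, s.contour_khz.size - 1)] * 1000.0
        else:
            f_inst = np.interp(tt, s.contour_times_s, s.contour_khz) * 1000.0
        phase = 2.0 * np.pi * np.cumsum(f_inst) / sample_rate
        amp = 10.0 ** (s.amplitude_db / 20.0)
        tone = amp * np.sin(phase)
        # cosine edge ramps suppress onset/offset clicks
        r = min(int(_EDGE_RAMP_S * sample_rate), m // 4)
        if r > 0:
            ramp = 0.5 * (1.0 - np.cos(np.pi * np.arange(r) / r))
            tone[:r] *= ramp
            tone[-r:] *= ramp[::-1]
        noise_amp = amp * (1.0 - s.tonality)
        tone = tone + noise_amp * rng.standard_normal(m)
        sig[i0 : i0 + m] += tone
        truth_rows.append(
            {
                "onset_s": i0 / sample_rate,
                "offset_s": (i0 + m) / sample_rate,
                "type": s.type.value,
                "amplitude_db": s.amplitude_db,
            }
        )
    np.clip(sig, -1.0, 1.0, out=sig)
    truth = pd.DataFrame(
        truth_rows, columns=["onset_s", "offset_s", "type", "amplitude_db"]
    )
    return sig, truth


def write_wav(path, signal: np.ndarray, sample_rate: float = 250_000.0) -> None:
    """Write a float signal in [-1, 1] as 16-bit PCM WAV."""
    x = np.clip(np.asarray(signal, dtype=float), -1.0, 1.0)
    wavfile.write(path, int(sample_rate), np.round(x * 32767.0).astype(np.int16))


def read_wav(path) -> tuple[np.ndarray, float]:
    """Read a PCM WAV into float in [-1, 1]; returns (signal, sample_rate)."""
    sr, data = wavfile.read(path)
    if data.ndim > 1:
        data = data[:, 0]
    if data.dtype == np.int16:
        x = data.astype(float) / 32768.0
    elif data.dtype == np.int32:
        x = data.astype(float) / 2147483648.0
    elif data.dtype == np.uint8:
        x = (data.astype(float) - 128.0) / 128.0
    else:
        x = data.astype(float)
    return x, float(sr)
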