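"""Spectrogram computation, syllable segmentation and per-syllable features.

The measurement chain follows the standard Avisoft-style workflow for mouse
USV recordings: a flat-top windowed STFT (512-point FFT, 50% overlap at a
250 kHz sampling rate), a configurable dB floor standing in for hardware
noise reduction, silence-gap segmentation, and per-syllable measurements
taken on four spectra — the first frame ("start"), the middle frame
("center"), the last frame ("end") and the frame of maximum amplitude
("max").  From each spectrum we take peak frequency (argmax), peak
amplitude, minimum/maximum frequency at a -20 dB threshold relative to the
peak, bandwidth (max - min, exactly), and spectral entropy (Wiener entropy:
the geometric/arithmetic mean ratio of the linear power spectrum, bounded
[0, 1]; tonal whistles score low (< 0.3), broadband noise high (> 0.4)).
Duration (t_off - t_on) completes the 25-variable vector.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import ShortTimeFFT, get_window

from .simulate import FEATURE_COLUMNS

__all__ = [
    "SpectrogramParams",
    "Spectrogram",
    "Syllable",
    "compute_spectrogram",
    "segment_syllables",
    "extract_features",
    "extract_feature_table",
    "wiener_entropy",
]


@dataclass(frozen=True)
class SpectrogramParams:
    """STFT parameters.

    ``noise_floor_db`` is a single configurable floor (dB re full scale)
    applied to the magnitude spectrogram before segmentation; the original
    hardware's two-number noise-reduction setting is not reproducible
    verbatim, so one floor stands in for it.
    """

    sample_rate: float = 250_000.0
    fft_length: int = 512
    overlap_fraction: float = 0.5
    window: str = "flattop"
    noise_floor_db: float = -90.0

    def __post_init__(self) -> None:
        n = self.fft_length
        if n < 2 or (n & (n - 1)) != 0:
            raise ValueError("fft_length must be a power of two")
        if not 0.0 <= self.overlap_fraction < 1.0:
            raise ValueError("overlap_fraction must lie in [0, 1)")

    @property
    def hop(self) -> int:
        return int(round(self.fft_length * (1.0 - self.overlap_fraction)))

    @property
    def frame_dt(self) -> float:
        return self.hop / self.sample_rate


@dataclass
class Spectrogram:
    """Time-frequency magnitude matrix in dB re full scale (frames x bins)."""

    db: np.ndarray  # (n_frames, n_bins), floored at params.noise_floor_db
    times: np.ndarray  # frame center times (s)
    freqs_hz: np.ndarray  # bin center frequencies (Hz)
    params: SpectrogramParams

    @property
    def n_frames(self) -> int:
        return self.db.shape[0]


@dataclass
class Syllable:
    """A segmented sound unit: frame span plus its per-frame spectra."""

    t_on: float
    t_off: float
    frame_slice: slice
    spectrogram: Spectrogram = field(repr=False)

    @property
    def frames_db(self) -> np.ndarray:
        return self.spectrogram.db[self.frame_slice]

    @property
    def frame_times(self) -> np.ndarray:
        return self.spectrogram.times[self.frame_slice]

    @property
    def n_frames(self) -> int:
        return self.frames_db.shape[0]

    @property
    def peak_contour_khz(self) -> np.ndarray:
        """Per-frame peak frequency (kHz) — the input to syllable typing.

        Frames whose peak amplitude falls more than 25 dB below the
        syllable's loudest frame are dropped: at onset/offset ramps the tone
        is too weak for the argmax to be meaningful and background noise
        would inject spurious frequency jumps.
        """
        db = self.frames_db
        frame_peak = db.max(axis=1)
        keep = frame_peak >= frame_peak.max() - 25.0
        idx = np.argmax(db[keep], axis=1)
        return self.spectrogram.freqs_hz[idx] / 1000.0

    @property
    def duration(self) -> float:
        return self.t_off - self.t_on


def compute_spectrogram(
    signal: np.ndarray, params: SpectrogramParams = SpectrogramParams()
) -> Spectrogram:
    """STFT magnitude in dB re full scale, floored at ``noise_floor_db``.

    A full-scale sine (amplitude 1.0) peaks near 0 dB.  Frame spacing is
    ``fft_length * (1 - overlap) / sample_rate``.
    """
    x = np.asarray(signal, dtype=float)
    if x.size == 0:
        raise ValueError("empty signal")
    if x.size < params.fft_length:
        raise ValueError(
            f"signal shorter ({x.size}) than fft_length ({params.fft_length})"
        )
    win = get_window(params.window, params.fft_length, fftbins=True)
    stft = ShortTimeFFT(
        win, hop=params.hop, fs=params.sample_rate, fft_mode="onesided"
    )
    mag = np.abs(stft.stft(x)).T  # frames x bins
    # scale so a unit-amplitude sine reads 0 dB at its bin
    ref = win.sum() / 2.0
    with np.errstate(divide="ignore"):
        db = 20.0 * np.log10(mag / ref)
    db = np.maximum(db, params.noise_floor_db)
    times = stft.t(x.size)
    freqs = stft.f
    return Spectrogram(db=db, times=np.asarray(times), freqs_hz=np.asarray(freqs), params=params)


def segment_syllables(
    spec: Spectrogram,
    gap_ms: float = 10.0,
    min_dur_ms: float = 5.0,
    threshold_db: float | None = None,
) -> list[Syllable]:
    """Silence-gap segmentation on supra-floor frames.

    A frame is active when any bin exceeds ``threshold_db`` (default: the
    spectrogram's noise floor plus 1 dB).  Active runs separated by gaps
    shorter than ``gap_ms`` are merged; runs shorter than ``min_dur_ms`` are
    discarded.  Silence yields an empty list.
    """
    if threshold_db is None:
        threshold_db = spec.params.noise_floor_db + 1.0
    active = np.any(spec.db > threshold_db, axis=1)
    if not active.any():
        return []
    dt = float(np.median(np.diff(spec.times))) if spec.n_frames > 1 else spec.params.frame_dt
    gap_frames = max(1, int(round(gap_ms / 1000.0 / dt)))
    min_frames = max(1, int(round(min_dur_ms / 1000.0 / dt)))

    # runs of active frames
    padded = np.concatenate([[False], active, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(int)))
    starts, stops = edges[::2], edges[1::2]

    # merge runs separated by short gaps
    merged: list[list[int]] = []
    for s, e in zip(starts, stops):
        if merged and s - merged[-1][1] < gap_frames:
            merged[-1][1] = e
        else:
            merged.append([int(s), int(e)])

    out = []
    for s, e in merged:
        if e - s < min_frames:
            continue
        out.append(
            Syllable(
                t_on=float(spec.times[s]),
                t_off=float(spec.times[e - 1] + dt),
                frame_slice=slice(s, e),
                spectrogram=spec,
            )
        )
    return out


def wiener_entropy(power: np.ndarray) -> float:
    """Spectral flatness of a linear power spectrum, in [0, 1].

    Geometric over arithmetic mean; 0 for a single-bin line spectrum
    (in the floor limit), 1 for a perfectly flat spectrum.
    """
    p = np.asarray(power, dtype=float)
    p = np.maximum(p, 1e-300)
    gm = float(np.exp(np.mean(np.log(p))))
    am = float(np.mean(p))
    return gm / am


class TooFewFramesError(ValueError):
    """Syllable has fewer than 3 frames; excluded from feature tables."""


def _spectrum_features(db: np.ndarray, freqs_hz: np.ndarray, band_rel_db: float) -> dict:
    i_peak = int(np.argmax(db))
    peak_db = float(db[i_peak])
    above = np.flatnonzero(db >= peak_db - band_rel_db)
    f_min = float(freqs_hz[above[0]]) / 1000.0
    f_max = float(freqs_hz[above[-1]]) / 1000.0
    power = 10.0 ** (db / 10.0)
    return {
        "pF": float(freqs_hz[i_peak]) / 1000.0,
        "pAMP": peak_db,
        "minF": f_min,
        "maxF": f_max,
        "band": f_max - f_min,
        "ent": wiener_entropy(power),
    }


def extract_features(s: Syllable, band_rel_db: float = 20.0) -> dict[str, float]:
    """The 24 per-spectrum variables plus duration for one syllable.

    Start/center/end spectra are the first, middle (index ``(n-1)//2``,
    tie toward earlier) and last frame; the max spectrum is the frame whose
    peak amplitude is highest.  min/max frequency use a ``band_rel_db``
    threshold below that spectrum's peak, so min <= peak <= max and
    band = max - min hold exactly.

    Raises
    ------
    TooFewFramesError
        If the syllable spans fewer than 3 frames.
    """
    db = s.frames_db
    n = db.shape[0]
    if n < 3:
        raise TooFewFramesError(f"syllable at t={s.t_on:.4f}s has {n} frames")
    freqs = s.spectrogram.freqs_hz
    frames = {
        "start": db[0],
        "end": db[-1],
        "center": db[(n - 1) // 2],
        "max": db[int(np.argmax(db.max(axis=1)))],
    }
    out: dict[str, float] = {}
    for pos, spec_db in frames.items():
        f = _spectrum_features(spec_db, freqs, band_rel_db)
        for key, val in f.items():
            out[f"{key}{pos}"] = val
    out["duration"] = s.duration
    return out


def extract_feature_table(
    syllables: list[Syllable],
    band_rel_db: float = 20.0,
    meta: dict | None = None,
) -> pd.DataFrame:
    """Feature rows for a list of syllables; too-short syllables are skipped.

    ``meta`` entries (e.g. individual id, group labels) are prepended to every
    row.  Column order follows the canonical 24-variable + duration layout.
    """
    rows = []
    for k, s in enumerate(syllables):
        try:
            feats = extract_features(s, band_rel_db)
        except TooFewFramesError:
            continue
        row = dict(meta or {})
        row.update({"syllable_index": k, "onset_s": s.t_on})
        row.update(feats)
        rows.append(row)
    meta_cols = list(meta or {}) + ["syllable_index", "onset_s"]
    cols = meta_cols + list(FEATURE_COLUMNS)
    if not rows:
        return pd.DataFrame(columns=cols)
    return pd.DataFrame(rows)[cols]
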