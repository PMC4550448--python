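"""Synthetic USV colonies with the statistical structure of wild-derived *Mus* groups.

This module generates individuals, syllable sequences and (via :mod:`usvkit.audio`)
waveforms for eight default groups spanning two species: four *M. m. musculus*
populations, one *M. m. domesticus* population, two musculus x domesticus hybrid
lines, and *M. spicilegus*.  The defaults encode the group structure the
downstream analyses assume:

* per-group vocalizer probabilities spanning 0.29-0.87;
* heavily right-skewed latencies to first call (log-normal, 0.5-1437.5 s);
* overdispersed 30-min syllable counts (negative binomial, 31-2661);
* seven syllable types with group-specific repertoire weights, frequency
  upsweeps dominant (~56% on average) and the rare types (chevron,
  2-frequency-step) absent from some groups;
* species contrasts in the syllable features: *M. spicilegus* calls at higher
  peak frequency (74.69 vs 69.75 kHz), lower amplitude (-22.59 vs -18.0 dBFS),
  higher entropy (0.199 vs 0.187) and shorter duration (0.030 vs 0.0325 s)
  than *M. musculus*.

Feature emission uses a block-structured Gaussian model: the 24 spectral
variables (12 frequency, 4 amplitude, 4 bandwidth, 4 entropy) are drawn with
within-block correlation matrices calibrated so that a correlation-matrix PCA
per block recovers the canonical variance fractions (frequency axes ~79%/9%,
amplitude ~83%, bandwidth ~42%, entropy ~66%).  Each variable decomposes into
a group+type mean, a per-individual "voice" effect and per-syllable noise, so
group means are recoverable at large n while individuals remain distinctive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calltypes import CANONICAL_TYPES, SyllableType

__all__ = [
    "GroupSpec",
    "SyllableSpec",
    "SyntheticIndividual",
    "default_groups",
    "build_colony",
    "build_default_colony",
    "build_study_colony",
    "emit_feature_table",
    "colony_summary",
    "FEATURE_COLUMNS",
    "FREQ_VARS",
    "AMP_VARS",
    "BAND_VARS",
    "ENT_VARS",
]

# ---------------------------------------------------------------------------
# feature naming (matching the conventional per-spectrum measurement table)

_POSITIONS = ("start", "end", "center", "max")
FREQ_VARS = tuple(f"pF{p}" for p in _POSITIONS) + tuple(
    f"minF{p}" for p in _POSITIONS
) + tuple(f"maxF{p}" for p in _POSITIONS)
AMP_VARS = tuple(f"pAMP{p}" for p in _POSITIONS)
BAND_VARS = tuple(f"band{p}" for p in _POSITIONS)
ENT_VARS = tuple(f"ent{p}" for p in _POSITIONS)
FEATURE_COLUMNS = FREQ_VARS + AMP_VARS + BAND_VARS + ENT_VARS + ("duration",)

# ---------------------------------------------------------------------------
# within-block correlation calibration
#
# Frequency block: the 12 variables are 4 spectrum positions x {peak, min,
# max}; min/max track the peak, so the block correlation is governed by the
# 4x4 position matrix with correlation `a` among end/center/max and `c`
# between start and the rest (the start spectrum decorrelates because
# frequency-modulated calls begin away from their dominant frequency).
# The constants are the *noise* correlations; the record-level correlation
# that a PCA sees also contains the between-type, between-position and
# between-group mean structure, so the constants are calibrated such that a
# per-block correlation-matrix PCA on individual x type records under the
# default study conditions recovers the canonical variance fractions
# (frequency ~79.5%/9.3%, amplitude ~83%, bandwidth ~42%, entropy ~66%).
_FREQ_A = 0.79  # end/center/max mutual noise correlation
_FREQ_C = 0.71  # start vs the rest
_AMP_R = 0.745
_BAND_R = 0.15
_ENT_R = 0.515


def _pos_corr_freq() -> np.ndarray:
    r = np.full((4, 4), _FREQ_A)
    r[0, :] = r[:, 0] = _FREQ_C
    np.fill_diagonal(r, 1.0)
    return r


def _equicorr(r: float) -> np.ndarray:
    m = np.full((4, 4), r)
    np.fill_diagonal(m, 1.0)
    return m


_CHOL = {
    "freq": np.linalg.cholesky(_pos_corr_freq()),
    "amp": np.linalg.cholesky(_equicorr(_AMP_R)),
    "band": np.linalg.cholesky(_equicorr(_BAND_R)),
    "ent": np.linalg.cholesky(_equicorr(_ENT_R)),
}

# variance partition of the spectral blocks: the individual "voice" SD is
# _FEAT_IND_SD_FRAC * sigma; per-syllable noise is _FEAT_SYL_SD_FRAC * sigma,
# sized so that an individual-mean record over a typical ~15-syllable type
# window has variance ~sigma^2 (0.7^2 + 2.77^2/15 ~ 1).  Keeping the
# individual share moderate matters: individual x type records of one male
# appear on both sides of a classification split, and an overly distinctive
# voice would let flexible classifiers recognize males rather than
# populations.  Duration keeps its own partition (log scale).
_FEAT_IND_SD_FRAC = 0.7
_FEAT_SYL_SD_FRAC = 2.77
_IND_SD_FRAC = 0.95
_SYL_SD_FRAC = 1.0

# ---------------------------------------------------------------------------
# per-type mean structure (offsets are re-centered per group by repertoire
# weight so that group means equal the GroupSpec base values exactly)

_T = SyllableType
_TYPE_ORDER = CANONICAL_TYPES

# shift of the type's dominant frequency relative to the group base (kHz)
_TYPE_FREQ_OFF = {
    _T.FREQUENCY_UPSWEEP: 2.0,
    _T.FREQUENCY_DOWNSWEEP: -2.0,
    _T.CONSTANT_MODULATED: 0.0,
    _T.U_SHAPED: -1.0,
    _T.U_SHAPED_INVERTED: 3.0,
    _T.ONE_FREQUENCY_STEP: 1.0,
    _T.TWO_FREQUENCY_STEP: 4.0,
}
# start/end/center spectrum frequency offsets relative to the type's max
# spectrum, from the contour shape (kHz); order: (start, end, center, max)
_TYPE_POS_FREQ = {
    _T.FREQUENCY_UPSWEEP: (-4.36, 4.36, 0.0, 1.01),
    _T.FREQUENCY_DOWNSWEEP: (2.35, -2.35, 0.0, -0.34),
    _T.CONSTANT_MODULATED: (0.0, 0.0, 0.0, 0.0),
    _T.U_SHAPED: (1.88, 1.88, -1.88, 0.34),
    _T.U_SHAPED_INVERTED: (-1.88, -1.88, 1.88, 1.34),
    _T.ONE_FREQUENCY_STEP: (-3.35, 3.35, 0.0, 0.67),
    _T.TWO_FREQUENCY_STEP: (-4.02, 4.02, 0.0, 1.01),
}
_TYPE_AMP_OFF = {
    _T.FREQUENCY_UPSWEEP: 0.5,
    _T.FREQUENCY_DOWNSWEEP: -0.5,
    _T.CONSTANT_MODULATED: 1.5,
    _T.U_SHAPED: 0.0,
    _T.U_SHAPED_INVERTED: -0.5,
    _T.ONE_FREQUENCY_STEP: -1.5,
    _T.TWO_FREQUENCY_STEP: -2.5,
}
_AMP_POS = (-3.0, -3.0, -1.5, 0.0)
_TYPE_ENT_OFF = {
    _T.FREQUENCY_UPSWEEP: 0.0,
    _T.FREQUENCY_DOWNSWEEP: 0.0,
    _T.CONSTANT_MODULATED: -0.008,
    _T.U_SHAPED: 0.002,
    _T.U_SHAPED_INVERTED: 0.004,
    _T.ONE_FREQUENCY_STEP: 0.003,
    _T.TWO_FREQUENCY_STEP: 0.005,
}
_ENT_POS = (0.008, 0.008, 0.002, 0.0)
# instantaneous (per-spectrum) bandwidth mean per type (kHz), group-invariant
_TYPE_BAND_MEAN = {
    _T.FREQUENCY_UPSWEEP: 3.5,
    _T.FREQUENCY_DOWNSWEEP: 3.0,
    _T.CONSTANT_MODULATED: 1.5,
    _T.U_SHAPED: 3.0,
    _T.U_SHAPED_INVERTED: 3.2,
    _T.ONE_FREQUENCY_STEP: 2.5,
    _T.TWO_FREQUENCY_STEP: 2.8,
}
_BAND_POS = (0.6, 0.6, 0.0, -0.2)
# multiplicative duration factor per type (step calls are longer compounds)
_TYPE_DUR_MULT = {
    _T.FREQUENCY_UPSWEEP: 1.10,
    _T.FREQUENCY_DOWNSWEEP: 0.95,
    _T.CONSTANT_MODULATED: 0.80,
    _T.U_SHAPED: 1.00,
    _T.U_SHAPED_INVERTED: 1.05,
    _T.ONE_FREQUENCY_STEP: 1.35,
    _T.TWO_FREQUENCY_STEP: 1.60,
}
# contour frequency-modulation extent per type: (mean, sd, lo, hi) kHz;
# clipping keeps every draw safely on its type's side of the decision rules
_TYPE_EXTENT = {
    _T.FREQUENCY_UPSWEEP: (15.0, 2.0, 11.0, 25.0),
    _T.FREQUENCY_DOWNSWEEP: (8.0, 1.5, 6.0, 20.0),
    _T.CONSTANT_MODULATED: (0.8, 0.3, 0.1, 1.8),
    _T.U_SHAPED: (6.5, 1.0, 4.8, 15.0),
    _T.U_SHAPED_INVERTED: (6.5, 1.0, 4.8, 15.0),
    _T.ONE_FREQUENCY_STEP: (14.0, 1.5, 12.0, 20.0),
    _T.TWO_FREQUENCY_STEP: (14.0, 1.5, 12.0, 20.0),
}

_GAP_RANGE_S = (0.03, 0.94)  # inter-syllable silence, uniform
_LATENCY_RANGE_S = (0.5, 1437.5)  # observed latency range; draws truncated
_COUNT_RANGE = (31, 2661)  # observed 30-min syllable count range
_CONTOUR_KHZ_CLIP = (35.0, 110.0)
_CONTOUR_DT_S = 0.001


@dataclass(frozen=True)
class GroupSpec:
    """Generative parameters for one population / species group.

    Frequency, amplitude, entropy and duration bases are the group means of
    pFmax, pAMPmax, entmax and syllable duration; per-type offsets are
    re-centered by repertoire weight so the group mean equals the base.
    """

    name: str
    species: str
    subspecies: str
    p_vocalizer: float
    latency_lognorm: tuple[float, float]  # (mu, sigma) of log-seconds
    count_nb: tuple[float, float]  # (mean, dispersion)
    repertoire_weights: np.ndarray  # 7-vector over CANONICAL_TYPES
    peak_khz: float
    amp_db: float
    entropy: float
    duration_s: float
    sigma_freq_khz: float = 8.5
    sigma_amp_db: float = 6.0
    sigma_entropy: float = 0.016
    sigma_band_khz: float = 1.2
    sigma_log_duration: float = 0.45
    dirichlet_conc: float = 50.0

    def __post_init__(self) -> None:
        w = np.asarray(self.repertoire_weights, dtype=float)
        if w.shape != (7,):
            raise ValueError("repertoire_weights must be a 7-vector")
        if np.any(w < 0):
            raise ValueError("repertoire_weights must be nonnegative")
        if abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("repertoire_weights must sum to 1 within 1e-9")
        if not 0.0 <= self.p_vocalizer <= 1.0:
            raise ValueError("p_vocalizer must lie in [0, 1]")
        if self.duration_s <= 0:
            raise ValueError("duration mean must be positive")
        for s in (
            self.sigma_freq_khz,
            self.sigma_amp_db,
            self.sigma_entropy,
            self.sigma_band_khz,
            self.sigma_log_duration,
        ):
            if s < 0:
                raise ValueError("all SDs must be nonnegative")
        object.__setattr__(self, "repertoire_weights", w)

    @property
    def population(self) -> str:
        return self.name

    def _record_weights(self) -> np.ndarray:
        """Expected per-type weight of individual x type mean records.

        Group means are quoted at the record level (one individual-mean
        record per type present in a male's first-100-syllable window), so
        type offsets are re-centered by the probability that each type
        appears in that window.  Individual repertoires are
        Dirichlet-perturbed, so presence follows the Beta-binomial
        P(absent) = E_Beta(a,b)[(1-p)^n] with a = w*conc, b = conc - a, and
        the window n is the expected min(count, 100) under the group's
        count distribution.
        """
        cached = getattr(self, "_record_weights_cache", None)
        if cached is not None:
            return cached
        from scipy.special import gammaln
        from scipy.stats import nbinom

        mean, disp = self.count_nb
        p_nb = disp / (disp + mean)
        lo, hi = _COUNT_RANGE
        k = np.arange(0, hi + 1)
        pmf = nbinom.pmf(k, disp, p_nb)
        counts = np.minimum(np.clip(k, lo, hi), 100)
        n_win = float(counts @ pmf + 100.0 * (1.0 - pmf.sum()))

        w = self.repertoire_weights
        conc = self.dirichlet_conc
        present = np.zeros_like(w)
        alive = w > 0
        a = np.maximum(w[alive] * conc, 1e-3)
        b = conc - a
        log_absent = (
            gammaln(b + n_win) + gammaln(a + b) - gammaln(b) - gammaln(a + b + n_win)
        )
        present[alive] = 1.0 - np.exp(log_absent)
        total = present.sum()
        out = present / total if total > 0 else w
        object.__setattr__(self, "_record_weights_cache", out)
        return out

    # re-centerings so group record-level means land on the stated bases
    def _centered_freq_off(self) -> dict[SyllableType, float]:
        w = self._record_weights()
        total = np.array(
            [_TYPE_FREQ_OFF[t] + _TYPE_POS_FREQ[t][3] for t in _TYPE_ORDER]
        )
        shift = float(w @ total)
        return {t: _TYPE_FREQ_OFF[t] - shift for t in _TYPE_ORDER}

    def _centered_amp_off(self) -> dict[SyllableType, float]:
        w = self._record_weights()
        shift = float(w @ np.array([_TYPE_AMP_OFF[t] for t in _TYPE_ORDER]))
        return {t: _TYPE_AMP_OFF[t] - shift for t in _TYPE_ORDER}

    def _centered_ent_off(self) -> dict[SyllableType, float]:
        w = self._record_weights()
        shift = float(w @ np.array([_TYPE_ENT_OFF[t] for t in _TYPE_ORDER]))
        return {t: _TYPE_ENT_OFF[t] - shift for t in _TYPE_ORDER}

    def _centered_dur_mult(self) -> dict[SyllableType, float]:
        w = self._record_weights()
        shift = float(w @ np.array([_TYPE_DUR_MULT[t] for t in _TYPE_ORDER]))
        return {t: _TYPE_DUR_MULT[t] / shift for t in _TYPE_ORDER}

    def contour_params(self) -> dict[SyllableType, dict[str, tuple[float, float]]]:
        """Per-type (mean, sd) of start frequency, extent, duration, amplitude, tonality."""
        freq_off = self._centered_freq_off()
        amp_off = self._centered_amp_off()
        dur_mult = self._centered_dur_mult()
        out: dict[SyllableType, dict[str, tuple[float, float]]] = {}
        for t in _TYPE_ORDER:
            mu_f = self.peak_khz + freq_off[t]
            ext_mean, ext_sd, _, _ = _TYPE_EXTENT[t]
            out[t] = {
                "start_khz": (mu_f + _TYPE_POS_FREQ[t][0], 0.7 * self.sigma_freq_khz),
                "extent_khz": (ext_mean, ext_sd),
                "duration_s": (self.duration_s * dur_mult[t], self.sigma_log_duration),
                "amplitude_db": (self.amp_db + amp_off[t], 0.5 * self.sigma_amp_db),
                "tonality": (0.92, 0.03),
            }
        return out


@dataclass
class SyllableSpec:
    """One synthetic syllable: its type, timing and frequency contour."""

    type: SyllableType
    t_start: float
    duration_s: float
    contour_times_s: np.ndarray  # relative to syllable onset
    contour_khz: np.ndarray
    interp: str  # 'linear' | 'previous' (step contours hold then jump)
    amplitude_db: float
    tonality: float


@dataclass
class SyntheticIndividual:
    """One synthetic male with his vocal output (possibly empty)."""

    id: str
    group: GroupSpec
    is_vocalizer: bool
    latency_s: float | None
    n_syllables_30min: int
    syllables: list[SyllableSpec] = field(default_factory=list)
    feature_seed: int = 0
    dur_log_effect: float = 0.0
    freq_shift_khz: float = 0.0


# ---------------------------------------------------------------------------
# default colony definition


def _g(
    name: str,
    species: str,
    subspecies: str,
    p_voc: float,
    lat_med_s: float,
    count_mean: float,
    weights: list[float],
    peak: float,
    amp: float,
    ent: float,
    dur: float,
    **kw,
) -> GroupSpec:
    w = np.asarray(weights, dtype=float)
    return GroupSpec(
        name=name,
        species=species,
        subspecies=subspecies,
        p_vocalizer=p_voc,
        latency_lognorm=(float(np.log(lat_med_s)), 1.1),
        count_nb=(count_mean, 1.3),
        repertoire_weights=w / w.sum(),
        peak_khz=peak,
        amp_db=amp,
        entropy=ent,
        duration_s=dur,
        **kw,
    )


def default_groups() -> list[GroupSpec]:
    """The eight default groups with their study-condition parameters.

    Weights are over (upsweep, downsweep, constant, U, chevron, 1-step,
    2-step); zero weight marks a type absent from that group's repertoire.
    """
    ms_kw = dict(
        sigma_freq_khz=7.0,
        sigma_amp_db=3.5,
        sigma_entropy=0.007,
        sigma_log_duration=0.23,
    )
    return [
        _g("M.m.m.1", "M.m.", "M.m.m.", 0.87, 11, 1057,
           [0.62, 0.14, 0.13, 0.055, 0.014, 0.011, 0.0],
           68.30, -17.0, 0.180, 0.0340),
        _g("M.m.m.2", "M.m.", "M.m.m.", 0.39, 400, 350,
           [0.70, 0.13, 0.10, 0.040, 0.028, 0.002, 0.0],
           70.80, -18.5, 0.190, 0.0315),
        _g("M.m.m.3", "M.m.", "M.m.m.", 0.31, 668, 256,
           [0.44, 0.25, 0.19, 0.090, 0.004, 0.008, 0.001],
           71.20, -19.0, 0.193, 0.0310),
        _g("M.m.m.4", "M.m.", "M.m.m.", 0.86, 15, 950,
           [0.56, 0.006, 0.21, 0.014, 0.018, 0.011, 0.004],
           68.80, -17.5, 0.183, 0.0335),
        _g("M.m.d.", "M.m.", "M.m.d.", 0.29, 300, 300,
           [0.45, 0.15, 0.15, 0.080, 0.080, 0.060, 0.030],
           69.75, -18.0, 0.187, 0.0325),
        _g("Hybrid 1", "M.m.", "Hybrid", 0.50, 100, 400,
           [0.50, 0.18, 0.14, 0.070, 0.050, 0.040, 0.020],
           69.30, -18.2, 0.186, 0.0320),
        _g("Hybrid 2", "M.m.", "Hybrid", 0.58, 250, 450,
           [0.55, 0.15, 0.14, 0.080, 0.040, 0.030, 0.010],
           70.20, -18.3, 0.189, 0.0325),
        _g("M.s.", "M.s.", "M.s.", 0.71, 150, 600,
           [0.50, 0.022, 0.24, 0.002, 0.160, 0.018, 0.008],
           74.69, -22.59, 0.199, 0.0300, **ms_kw),
    ]


# study vocalizer counts per group (recording continued until reached)
STUDY_VOCALIZER_TARGETS = {
    "M.m.m.1": 10, "M.m.m.2": 10, "M.m.m.3": 10, "M.m.m.4": 10,
    "M.m.d.": 4, "Hybrid 1": 5, "Hybrid 2": 7, "M.s.": 10,
}


# ---------------------------------------------------------------------------
# contour construction


def _build_contour(
    t: SyllableType,
    duration_s: float,
    center_khz: float,
    extent_khz: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, str]:
    n = max(5, int(round(duration_s / _CONTOUR_DT_S)) + 1)
    times = np.linspace(0.0, duration_s, n)
    u = times / duration_s  # in [0, 1]
    e = extent_khz
    if t is _T.FREQUENCY_UPSWEEP:
        f = center_khz - e / 2 + e * u
        kind = "linear"
    elif t is _T.FREQUENCY_DOWNSWEEP:
        f = center_khz + e / 2 - e * u
        kind = "linear"
    elif t is _T.CONSTANT_MODULATED:
        f = center_khz + (e / 2) * np.sin(2 * np.pi * 1.5 * u)
        kind = "linear"
    elif t is _T.U_SHAPED:
        f = (center_khz - e / 3) + e * (2 * u - 1) ** 2
        kind = "linear"
    elif t is _T.U_SHAPED_INVERTED:
        f = (center_khz + e / 3) - e * (2 * u - 1) ** 2
        kind = "linear"
    elif t is _T.ONE_FREQUENCY_STEP:
        tau = rng.uniform(0.35, 0.65)
        f = np.where(u < tau, center_khz - e / 2, center_khz + e / 2)
        kind = "previous"
    elif t is _T.TWO_FREQUENCY_STEP:
        tau1 = rng.uniform(0.25, 0.4)
        tau2 = rng.uniform(0.6, 0.75)
        e2 = e * rng.uniform(0.85, 1.15)
        f = np.where(u < tau1, center_khz - e / 2,
                     np.where(u < tau2, center_khz + e / 2,
                              center_khz + e / 2 - e2))
        kind = "previous"
    else:  # pragma: no cover - generator never emits UNCLASSIFIED
        raise ValueError(f"cannot build contour for {t}")
    f = np.clip(f, *_CONTOUR_KHZ_CLIP)
    return times, f, kind


def _draw_syllables(
    group: GroupSpec,
    n: int,
    latency_s: float,
    rng: np.random.Generator,
    dur_log_effect: float,
    freq_shift: float,
) -> list[SyllableSpec]:
    if n == 0:
        return []
    w = group.repertoire_weights
    conc = group.dirichlet_conc
    # individual repertoire: Dirichlet-perturbed group weights; zero-weight
    # types stay impossible for the group
    alive = w > 0
    w_ind = np.zeros_like(w)
    w_ind[alive] = rng.dirichlet(np.maximum(w[alive] * conc, 1e-3))
    types = rng.choice(len(_TYPE_ORDER), size=n, p=w_ind)

    freq_off = group._centered_freq_off()
    amp_off = group._centered_amp_off()
    dur_mult = group._centered_dur_mult()
    s_lat = group.sigma_log_duration
    var_corr = 0.5 * (s_lat**2) * (_IND_SD_FRAC**2 + _SYL_SD_FRAC**2)

    out: list[SyllableSpec] = []
    t_cursor = latency_s
    for i in range(n):
        st = _TYPE_ORDER[int(types[i])]
        dur = group.duration_s * dur_mult[st] * float(
            np.exp(dur_log_effect + s_lat * _SYL_SD_FRAC * rng.standard_normal() - var_corr)
        )
        dur = float(np.clip(dur, 0.005, 0.4))
        ext_mean, ext_sd, lo, hi = _TYPE_EXTENT[st]
        extent = float(np.clip(rng.normal(ext_mean, ext_sd), lo, hi))
        center = group.peak_khz + freq_off[st] + freq_shift + 2.0 * rng.standard_normal()
        times, freqs, kind = _build_contour(st, dur, center, extent, rng)
        amp = group.amp_db + amp_off[st] + 0.5 * group.sigma_amp_db * rng.standard_normal()
        ton = float(np.clip(rng.normal(0.92, 0.03), 0.70, 0.99))
        out.append(
            SyllableSpec(
                type=st,
                t_start=t_cursor,
                duration_s=dur,
                contour_times_s=times,
                contour_khz=freqs,
                interp=kind,
                amplitude_db=float(amp),
                tonality=ton,
            )
        )
        t_cursor += dur + rng.uniform(*_GAP_RANGE_S)
    return out


# ---------------------------------------------------------------------------
# colony construction


def _make_individual(
    group: GroupSpec,
    uid: str,
    rng: np.random.Generator,
    max_syllables: int,
) -> SyntheticIndividual:
    is_voc = bool(rng.random() < group.p_vocalizer)
    feature_seed = int(rng.integers(0, 2**31 - 1))
    if not is_voc:
        return SyntheticIndividual(
            id=uid, group=group, is_vocalizer=False, latency_s=None,
            n_syllables_30min=0, syllables=[], feature_seed=feature_seed,
        )
    mu, sig = group.latency_lognorm
    latency = float(np.clip(np.exp(rng.normal(mu, sig)), *_LATENCY_RANGE_S))
    mean, disp = group.count_nb
    count = int(rng.negative_binomial(disp, disp / (disp + mean)))
    count = int(np.clip(count, *_COUNT_RANGE))
    dur_log_effect = group.sigma_log_duration * _IND_SD_FRAC * rng.standard_normal()
    freq_shift = 0.7 * group.sigma_freq_khz * rng.standard_normal()
    syls = _draw_syllables(
        group, min(count, max_syllables), latency, rng, dur_log_effect, freq_shift
    )
    return SyntheticIndividual(
        id=uid, group=group, is_vocalizer=True, latency_s=latency,
        n_syllables_30min=count, syllables=syls, feature_seed=feature_seed,
        dur_log_effect=dur_log_effect, freq_shift_khz=freq_shift,
    )


def build_colony(
    groups: list[GroupSpec],
    seed: int,
    n_per_group: int = 10,
    max_syllables: int = 150,
) -> list[SyntheticIndividual]:
    """Draw ``n_per_group`` males per group; vocalizer status is Bernoulli.

    Syllable sequences are generated up to ``max_syllables`` per male (every
    per-syllable analysis uses at most the first 100); the full 30-min count
    is kept in ``n_syllables_30min``.  Identical seeds give identical output.
    """
    if n_per_group < 1:
        raise ValueError("n_per_group must be >= 1")
    rng = np.random.default_rng(seed)
    colony: list[SyntheticIndividual] = []
    for group in groups:
        for i in range(n_per_group):
            colony.append(
                _make_individual(group, f"{group.name}-{i + 1:03d}", rng, max_syllables)
            )
    return colony


def build_default_colony(
    seed: int, n_per_group: int = 10, max_syllables: int = 150
) -> list[SyntheticIndividual]:
    """Default eight-group colony (see :func:`default_groups`)."""
    return build_colony(default_groups(), seed, n_per_group, max_syllables)


def build_study_colony(
    seed: int,
    targets: dict[str, int] | None = None,
    max_syllables: int = 150,
    max_recruits_per_group: int = 200,
) -> list[SyntheticIndividual]:
    """Recruit males per group until the study's vocalizer counts are reached.

    Mirrors the original sampling design (recording continued until a target
    number of vocalizers per population): 10 vocalizers for each *M.m.m.*
    population and *M.s.*, 4 for *M.m.d.*, 5 and 7 for the hybrid lines.
    Non-vocalizing recruits are kept (they carry the vocalizer-proportion
    information).
    """
    targets = dict(STUDY_VOCALIZER_TARGETS if targets is None else targets)
    rng = np.random.default_rng(seed)
    colony: list[SyntheticIndividual] = []
    for group in default_groups():
        want = targets.get(group.name, 0)
        got = 0
        i = 0
        while got < want and i < max_recruits_per_group:
            i += 1
            ind = _make_individual(group, f"{group.name}-{i:03d}", rng, max_syllables)
            colony.append(ind)
            got += int(ind.is_vocalizer)
        if got < want:
            raise RuntimeError(
                f"could not reach {want} vocalizers for {group.name} "
                f"within {max_recruits_per_group} recruits"
            )
    return colony


# ---------------------------------------------------------------------------
# feature-table emission (statistical bypass path; no audio involved)


def _emit_for_individual(ind: SyntheticIndividual, cap: int | None) -> list[dict]:
    g = ind.group
    rng = np.random.default_rng(ind.feature_seed)
    # individual voice: one correlated draw per block
    zf = _CHOL["freq"] @ rng.standard_normal(4) * (_FEAT_IND_SD_FRAC * g.sigma_freq_khz)
    za = _CHOL["amp"] @ rng.standard_normal(4) * (_FEAT_IND_SD_FRAC * g.sigma_amp_db)
    zb = _CHOL["band"] @ rng.standard_normal(4) * (_FEAT_IND_SD_FRAC * g.sigma_band_khz)
    ze = _CHOL["ent"] @ rng.standard_normal(4) * (_FEAT_IND_SD_FRAC * g.sigma_entropy)

    freq_off = g._centered_freq_off()
    amp_off = g._centered_amp_off()
    ent_off = g._centered_ent_off()

    syls = ind.syllables if cap is None else ind.syllables[:cap]
    rows = []
    for k, syl in enumerate(syls):
        t = syl.type
        sf = _CHOL["freq"] @ rng.standard_normal(4) * (_FEAT_SYL_SD_FRAC * g.sigma_freq_khz)
        sa = _CHOL["amp"] @ rng.standard_normal(4) * (_FEAT_SYL_SD_FRAC * g.sigma_amp_db)
        sb = _CHOL["band"] @ rng.standard_normal(4) * (_FEAT_SYL_SD_FRAC * g.sigma_band_khz)
        se = _CHOL["ent"] @ rng.standard_normal(4) * (_FEAT_SYL_SD_FRAC * g.sigma_entropy)

        pf = g.peak_khz + freq_off[t] + np.asarray(_TYPE_POS_FREQ[t]) + zf + sf
        band = np.maximum(
            np.asarray(_TYPE_BAND_MEAN[t]) + np.asarray(_BAND_POS) + zb + sb, 0.2
        )
        amp = g.amp_db + amp_off[t] + np.asarray(_AMP_POS) + za + sa
        ent = np.clip(
            g.entropy + ent_off[t] + np.asarray(_ENT_POS) + ze + se, 0.001, 0.999
        )
        row = {
            "individual": ind.id,
            "population": g.name,
            "subspecies": g.subspecies,
            "species": g.species,
            "syllable_index": k,
            "onset_s": syl.t_start,
            "type": t.value,
        }
        for j, p in enumerate(_POSITIONS):
            row[f"pF{p}"] = pf[j]
            row[f"minF{p}"] = pf[j] - band[j] / 2
            row[f"maxF{p}"] = pf[j] + band[j] / 2
            row[f"pAMP{p}"] = amp[j]
            row[f"band{p}"] = band[j]
            row[f"ent{p}"] = ent[j]
        row["duration"] = syl.duration_s
        rows.append(row)
    return rows


_META_COLUMNS = (
    "individual", "population", "subspecies", "species",
    "syllable_index", "onset_s", "type",
)


def emit_feature_table(
    colony: list[SyntheticIndividual], cap: int | None = None
) -> pd.DataFrame:
    """Per-syllable feature records for a colony (one row per syllable).

    ``cap`` limits each male to his first ``cap`` syllables (pass 100 for the
    standard analysis window).  Deterministic given the colony: each male
    carries his own feature seed.  An all-silent colony yields an empty table
    with the full header.
    """
    if not colony:
        raise ValueError("colony is empty")
    rows: list[dict] = []
    for ind in colony:
        rows.extend(_emit_for_individual(ind, cap))
    cols = list(_META_COLUMNS) + list(FEATURE_COLUMNS)
    if not rows:
        return pd.DataFrame(columns=cols)
    return pd.DataFrame(rows, columns=cols)


def colony_summary(colony: list[SyntheticIndividual]) -> pd.DataFrame:
    """One row per male: group labels, vocalizer flag, latency and counts."""
    rows = [
        {
            "individual": ind.id,
            "population": ind.group.name,
            "subspecies": ind.group.subspecies,
            "species": ind.group.species,
            "is_vocalizer": ind.is_vocalizer,
            "latency_s": np.nan if ind.latency_s is None else ind.latency_s,
            "n_syllables_30min": ind.n_syllables_30min,
        }
        for ind in colony
    ]
    return pd.DataFrame(rows)
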