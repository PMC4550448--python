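"""Rule-based classification of USV syllables into seven categories.

Mouse ultrasonic syllables are conventionally sorted into a small set of
categories by the shape of their peak-frequency contour: rising sweeps,
falling sweeps, flat ("constant modulated") calls, U-shaped and chevron
(inverted-U) calls, and calls containing one or two instantaneous frequency
steps.  The decision rules operate on the frequency-modulation depth
(max - min of the contour, in kHz) and on adjacent-frame frequency jumps.

Decision order (first match wins):

1. count instantaneous jumps (|df| >= ``step_khz`` between adjacent frames):
   two jumps -> TWO_FREQUENCY_STEP, one -> ONE_FREQUENCY_STEP, three or
   more -> UNCLASSIFIED;
2. modulation <= 2 kHz -> CONSTANT_MODULATED;
3. monotone rise with modulation >= 10 kHz -> FREQUENCY_UPSWEEP;
4. monotone fall with modulation >= 5 kHz -> FREQUENCY_DOWNSWEEP;
5. single interior minimum (fall then rise) with modulation >= 4 kHz ->
   U_SHAPED; single interior maximum -> U_SHAPED_INVERTED;
6. otherwise UNCLASSIFIED (the published rules are not exhaustive; e.g. a
   3 kHz non-monotone wobble matches none of them).

"Monotone" is judged after a 3-frame median smoothing with a small reversal
tolerance, because raw per-frame argmax contours jitter by roughly one FFT
bin.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum

import numpy as np

__all__ = [
    "SyllableType",
    "ClassifierParams",
    "RepertoireProfile",
    "classify_contour",
    "build_repertoire",
]


class SyllableType(str, Enum):
    """The seven published syllable categories plus an explicit leftover bucket."""

    FREQUENCY_UPSWEEP = "Frequency Upsweep"
    FREQUENCY_DOWNSWEEP = "Frequency Downsweep"
    CONSTANT_MODULATED = "Constant Modulated"
    U_SHAPED = "U-Shaped"
    U_SHAPED_INVERTED = "U-Shaped Inverted"
    ONE_FREQUENCY_STEP = "1-Frequency-Step"
    TWO_FREQUENCY_STEP = "2-Frequency-Step"
    UNCLASSIFIED = "Unclassified"


#: The seven real categories, in canonical order (excludes UNCLASSIFIED).
CANONICAL_TYPES: tuple[SyllableType, ...] = (
    SyllableType.FREQUENCY_UPSWEEP,
    SyllableType.FREQUENCY_DOWNSWEEP,
    SyllableType.CONSTANT_MODULATED,
    SyllableType.U_SHAPED,
    SyllableType.U_SHAPED_INVERTED,
    SyllableType.ONE_FREQUENCY_STEP,
    SyllableType.TWO_FREQUENCY_STEP,
)


@dataclass(frozen=True)
class ClassifierParams:
    """Thresholds of the contour decision rules (all in kHz).

    ``upsweep_khz``, ``downsweep_khz``, ``constant_khz`` and ``u_khz`` are the
    published modulation thresholds; ``step_khz`` (adjacent-frame jump that
    counts as an instantaneous step) and ``reversal_tol_khz`` (monotonicity
    slack after smoothing) are implementation choices, configurable here.
    """

    upsweep_khz: float = 10.0
    downsweep_khz: float = 5.0
    constant_khz: float = 2.0
    u_khz: float = 4.0
    step_khz: float = 10.0
    reversal_tol_khz: float = 1.0
    smooth_frames: int = 3


DEFAULT_CLASSIFIER = ClassifierParams()


def _median_smooth(x: np.ndarray, width: int) -> np.ndarray:
    if width <= 1 or x.size < width:
        return x
    # edge frames are kept as-is; median filtering must not erode real steps,
    # which an odd-width running median preserves
    from scipy.ndimage import median_filter

    return median_filter(x, size=width, mode="nearest")


def _monotone(x: np.ndarray, direction: int, tol: float) -> bool:
    """True if x is non-decreasing (direction=+1) / non-increasing (-1) within tol.

    The tolerance bounds the *cumulative* reversal (drop below the running
    maximum for a rise, or rise above the running minimum for a fall), so
    slow reversals cannot pass by staying under a per-step threshold.
    """
    if direction > 0:
        return bool(np.max(np.maximum.accumulate(x) - x) <= tol)
    return bool(np.max(x - np.minimum.accumulate(x)) <= tol)


def classify_contour(
    peak_contour_khz: np.ndarray,
    frame_times_s: np.ndarray | None = None,
    params: ClassifierParams = DEFAULT_CLASSIFIER,
) -> SyllableType:
    """Assign one syllable category to a peak-frequency contour.

    Parameters
    ----------
    peak_contour_khz
        Per-frame peak frequency in kHz, ordered in time.
    frame_times_s
        Optional frame times; only the ordering is used, so they may be
        omitted for uniformly spaced contours.
    params
        Decision thresholds.

    Returns
    -------
    SyllableType
        Exactly one label; contours with fewer than 3 points are
        UNCLASSIFIED (with a warning).
    """
    f = np.asarray(peak_contour_khz, dtype=float)
    if frame_times_s is not None:
        order = np.argsort(np.asarray(frame_times_s, dtype=float), kind="stable")
        f = f[order]
    if f.size < 3:
        warnings.warn("contour has fewer than 3 points; returning Unclassified", stacklevel=2)
        return SyllableType.UNCLASSIFIED

    smooth = _median_smooth(f, params.smooth_frames)

    # (i) instantaneous steps take precedence over every shape rule
    jumps = int(np.sum(np.abs(np.diff(smooth)) >= params.step_khz))
    if jumps == 2:
        return SyllableType.TWO_FREQUENCY_STEP
    if jumps == 1:
        return SyllableType.ONE_FREQUENCY_STEP
    if jumps >= 3:
        return SyllableType.UNCLASSIFIED

    modulation = float(smooth.max() - smooth.min())

    # (ii) flat calls
    if modulation <= params.constant_khz:
        return SyllableType.CONSTANT_MODULATED

    tol = params.reversal_tol_khz
    # (iii)/(iv) monotone sweeps
    if _monotone(smooth, +1, tol) and modulation >= params.upsweep_khz:
        return SyllableType.FREQUENCY_UPSWEEP
    if _monotone(smooth, -1, tol) and modulation >= params.downsweep_khz:
        return SyllableType.FREQUENCY_DOWNSWEEP

    # (v) single interior extremum
    if modulation >= params.u_khz:
        i_min = int(np.argmin(smooth))
        if 0 < i_min < smooth.size - 1:
            if _monotone(smooth[: i_min + 1], -1, tol) and _monotone(smooth[i_min:], +1, tol):
                return SyllableType.U_SHAPED
        i_max = int(np.argmax(smooth))
        if 0 < i_max < smooth.size - 1:
            if _monotone(smooth[: i_max + 1], +1, tol) and _monotone(smooth[i_max:], -1, tol):
                return SyllableType.U_SHAPED_INVERTED

    return SyllableType.UNCLASSIFIED


@dataclass
class RepertoireProfile:
    """Per-male syllable-type summary over the first ``cap`` syllables.

    ``repertoire_size`` counts distinct *canonical* types present (0-7);
    unclassified syllables occupy slots in the first-100 window but do not
    add to repertoire size.  ``type_proportions`` are over classified
    syllables and sum to 1 when any syllable was classified.
    """

    individual_id: str
    counts: dict[SyllableType, int] = field(default_factory=dict)
    n_used: int = 0

    @property
    def repertoire_size(self) -> int:
        return sum(
            1 for t in CANONICAL_TYPES if self.counts.get(t, 0) > 0
        )

    @property
    def type_proportions(self) -> dict[SyllableType, float]:
        n_classified = sum(self.counts.get(t, 0) for t in CANONICAL_TYPES)
        if n_classified == 0:
            return {t: 0.0 for t in CANONICAL_TYPES}
        return {t: self.counts.get(t, 0) / n_classified for t in CANONICAL_TYPES}


def build_repertoire(
    individual_id: str,
    types: list[SyllableType],
    cap: int = 100,
) -> RepertoireProfile:
    """Summarize the first ``cap`` classified syllables of one male.

    ``types`` must be ordered by syllable onset; only the first
    ``min(cap, len(types))`` entries are counted, mirroring the
    first-100-syllables analysis window.
    """
    used = types[: min(cap, len(types))]
    counts: dict[SyllableType, int] = {}
    for t in used:
        counts[t] = counts.get(t, 0) + 1
    return RepertoireProfile(individual_id=individual_id, counts=counts, n_used=len(used))
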