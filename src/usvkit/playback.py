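"""Female playback-preference analysis from zone-transition event logs.

The two-way choice apparatus has a shared Neutral zone and, per side, a
Middle zone (9-18 cm from the speaker), a Speaker zone (0-9 cm) and the
Fence (contact with the mesh in front of the speaker; scored as its own
zone, mutually exclusive with the Speaker zone).  A trial is 310 s of
playback; retention time in each zone is accumulated from timestamped zone
transitions, and preference is tested per aggregate (Fence; Fence+Speaker;
Fence+Speaker+Middle) with Wilcoxon signed-rank tests across females,
plus a binomial test of the side of first entry and a side-bias check on
physical left/right.  The latency of first entry into a never-entered side
is set to the trial length (310 s).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .npstats import StatResult, binomial_test, wilcoxon_signed_rank

__all__ = [
    "TRIAL_LENGTH_S",
    "ZONES",
    "PreferenceTrial",
    "ZoneTimes",
    "accumulate_zone_times",
    "preference_battery",
    "build_playback_sequence",
    "simulate_trial_log",
]

TRIAL_LENGTH_S = 310.0
ZONES = ("fence", "speaker", "middle")
SIDES = ("side1", "side2")
_GAP_RANGE_S = (0.03, 0.94)
_PHRASE_GAP_S = 1.0


@dataclass
class PreferenceTrial:
    """One female x one stimulus pair, with its zone-transition log.

    ``events`` has columns ``time_s`` (entry time), ``zone`` ("neutral" or
    one of fence/speaker/middle) and ``side`` ("side1"/"side2"; empty/NaN for
    neutral).  The female occupies each zone from its entry until the next
    event; the log starts at 0 in the neutral zone and the trial ends at
    ``TRIAL_LENGTH_S``.  ``stimulus_side1``/``stimulus_side2`` name the
    playbacks; ``side1_is_left`` records the physical counterbalancing.
    """

    female_id: str
    trial_id: str
    stimulus_side1: str
    stimulus_side2: str
    events: pd.DataFrame
    side1_is_left: bool = True


@dataclass
class ZoneTimes:
    """Retention times (s) per zone and side for one trial."""

    female_id: str
    trial_id: str
    neutral_s: float = 0.0
    times: dict[str, float] = field(default_factory=dict)  # (side, zone) -> s
    latency: dict[str, float] = field(
        default_factory=lambda: {s: TRIAL_LENGTH_S for s in SIDES}
    )
    first_side: str | None = None
    visits: dict[str, int] = field(default_factory=lambda: {s: 0 for s in SIDES})

    def zone(self, side: str, zone: str) -> float:
        return self.times.get((side, zone), 0.0)

    def aggregate(self, side: str, depth: str) -> float:
        """Cumulative retention time: 'F', 'F+S' or 'F+S+M'."""
        levels = {"F": 1, "F+S": 2, "F+S+M": 3}[depth]
        return sum(self.zone(side, z) for z in ZONES[:levels])

    @property
    def total(self) -> float:
        return self.neutral_s + sum(self.times.values())


def accumulate_zone_times(trial: PreferenceTrial) -> ZoneTimes:
    """Credit the interval between consecutive transitions to the occupied zone.

    Rejects unsorted or out-of-range logs with the offending line numbers.
    """
    ev = trial.events.reset_index(drop=True)
    times = ev["time_s"].to_numpy(dtype=float)
    bad = np.flatnonzero(np.diff(times) < 0) + 1
    if bad.size:
        raise ValueError(f"event log not time-ordered at line(s) {bad.tolist()}")
    out_of_range = np.flatnonzero((times < 0) | (times > TRIAL_LENGTH_S))
    if out_of_range.size:
        raise ValueError(f"event time outside [0, {TRIAL_LENGTH_S}] at line(s) {out_of_range.tolist()}")

    zt = ZoneTimes(female_id=trial.female_id, trial_id=trial.trial_id)
    # occupancy starts in the neutral zone at t = 0
    cur_zone, cur_side, t_prev = "neutral", None, 0.0
    rows = list(ev.itertuples(index=False))
    for row in rows:
        t = float(row.time_s)
        span = t - t_prev
        if cur_zone == "neutral":
            zt.neutral_s += span
        else:
            key = (cur_side, cur_zone)
            zt.times[key] = zt.times.get(key, 0.0) + span
        zone = str(row.zone).lower()
        side = None if zone == "neutral" else str(row.side)
        if zone != "neutral":
            if side not in SIDES:
                raise ValueError(f"unknown side {side!r} in event log")
            if zone not in ZONES:
                raise ValueError(f"unknown zone {zone!r} in event log")
            if zt.latency[side] >= TRIAL_LENGTH_S:
                zt.latency[side] = t
                if zt.first_side is None:
                    zt.first_side = side
            if cur_side != side:
                zt.visits[side] += 1
        cur_zone, cur_side, t_prev = zone, side, t
    span = TRIAL_LENGTH_S - t_prev
    if cur_zone == "neutral":
        zt.neutral_s += span
    else:
        zt.times[(cur_side, cur_zone)] = zt.times.get((cur_side, cur_zone), 0.0) + span
    return zt


def _median_iqr(x: np.ndarray) -> str:
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    return f"{med:.1f} ({q1:.1f}-{q3:.1f})"


def preference_battery(
    trials: list[PreferenceTrial],
    comparison: tuple[str, str] | None = None,
) -> dict[str, StatResult | pd.DataFrame]:
    """The full preference test set for one stimulus comparison.

    Per zone aggregate (F, F+S, F+S+M): Wilcoxon signed-rank of side1 vs
    side2 retention times (Z negative when side1 is preferred).  Plus a
    side-bias Wilcoxon on physical left vs right, an exact binomial test of
    first-entry counts, and a tidy summary table with medians and IQRs.

    All trials must share the same stimulus pair (pass ``comparison`` to
    assert it explicitly).
    """
    if len(trials) < 2:
        raise ValueError("need at least two trials")
    pairs = {(t.stimulus_side1, t.stimulus_side2) for t in trials}
    if len(pairs) > 1:
        raise ValueError(f"mismatched stimulus pairs in one battery: {sorted(pairs)}")
    if comparison is not None and pairs != {tuple(comparison)}:
        raise ValueError(f"trials carry pair {pairs}, expected {tuple(comparison)}")

    zts = [accumulate_zone_times(t) for t in trials]
    results: dict[str, StatResult | pd.DataFrame] = {}
    summary_rows = []
    for depth in ("F", "F+S", "F+S+M"):
        a = np.array([z.aggregate("side1", depth) for z in zts])
        b = np.array([z.aggregate("side2", depth) for z in zts])
        res = wilcoxon_signed_rank(a, b)
        results[depth] = res
        summary_rows.append(
            {
                "aggregate": depth,
                "side1_median_iqr": _median_iqr(a),
                "side2_median_iqr": _median_iqr(b),
                "Z": res.z,
                "p": res.p,
                "n": len(zts),
            }
        )
    results["summary"] = pd.DataFrame(summary_rows)

    # physical side bias: map side1/side2 back to left/right
    left = np.array(
        [
            z.aggregate("side1" if t.side1_is_left else "side2", "F+S")
            for z, t in zip(zts, trials)
        ]
    )
    right = np.array(
        [
            z.aggregate("side2" if t.side1_is_left else "side1", "F+S")
            for z, t in zip(zts, trials)
        ]
    )
    results["side_bias"] = wilcoxon_signed_rank(left, right)

    firsts = [z.first_side for z in zts if z.first_side is not None]
    k = sum(1 for f in firsts if f == "side1")
    results["initial_preference"] = binomial_test(k, len(firsts)) if firsts else None

    lat1 = np.array([z.latency["side1"] for z in zts])
    lat2 = np.array([z.latency["side2"] for z in zts])
    results["latency"] = wilcoxon_signed_rank(lat1, lat2)
    return results


def build_playback_sequence(
    syllable_pool: dict[str, list],
    target_count: int = 399,
    total_s: float = TRIAL_LENGTH_S,
    count_tolerance: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Plan a standardized playback from a pool of contributors' syllables.

    Contributors alternate in segments: 10 contributors give ten 30 s
    segments, a single contributor is repeated in five 61 s segments, and
    intermediate pool sizes split ~306 s evenly (4 contributors give four
    76.5 s segments).  Within segments, syllables are packed into phrases
    (inter-syllable gaps uniform on 0.03-0.94 s, 1 s between phrases) until
    the per-segment syllable budget is met.  The plan totals
    ``target_count`` +- ``count_tolerance`` syllables; a pool too small to
    reach the target raises with the shortfall.

    ``syllable_pool`` maps contributor id -> list of syllable durations (s)
    or SyllableSpec objects.
    """
    if not syllable_pool:
        raise ValueError("empty syllable pool")
    n_contrib = len(syllable_pool)

    def _dur(s) -> float:
        return float(s if isinstance(s, (int, float)) else s.duration_s)

    n_avail = sum(len(v) for v in syllable_pool.values())
    if n_avail < target_count - count_tolerance:
        raise ValueError(
            f"pool of {n_avail} syllables cannot reach target "
            f"{target_count} (shortfall {target_count - count_tolerance - n_avail})"
        )
    if n_contrib == 1:
        n_segments, seg_len = 5, 61.0
        contributors = list(syllable_pool) * 5
    elif n_contrib == 10:
        n_segments, seg_len = 10, 30.0
        contributors = list(syllable_pool)
    else:
        n_segments = n_contrib
        seg_len = round((total_s - 4.0) / n_contrib, 1)
        contributors = list(syllable_pool)

    rng = np.random.default_rng(seed)
    per_seg = [target_count // n_segments] * n_segments
    for i in range(target_count - sum(per_seg)):
        per_seg[i] += 1

    cursors = {c: 0 for c in syllable_pool}
    rows = []
    t_seg = 0.0
    for seg_idx, contrib in enumerate(contributors):
        budget = per_seg[seg_idx]
        t = t_seg
        placed = 0
        phrase_len = 0
        while placed < budget:
            pool = syllable_pool[contrib]
            i = cursors[contrib] % len(pool)
            cursors[contrib] += 1
            dur = _dur(pool[i])
            rows.append(
                {
                    "segment": seg_idx,
                    "contributor": contrib,
                    "t_start_s": round(t, 4),
                    "duration_s": dur,
                }
            )
            placed += 1
            phrase_len += 1
            if phrase_len >= 8:
                t += dur + _PHRASE_GAP_S
                phrase_len = 0
            else:
                t += dur + rng.uniform(*_GAP_RANGE_S)
        t_seg += seg_len
    plan = pd.DataFrame(rows)
    plan.attrs["n_segments"] = n_segments
    plan.attrs["segment_length_s"] = seg_len
    plan.attrs["n_syllables"] = len(plan)
    return plan


def simulate_trial_log(
    female_id: str,
    trial_id: str,
    stimulus_side1: str,
    stimulus_side2: str,
    preference: float = 1.0,
    seed: int = 0,
    mean_dwell_s: float = 15.0,
    side1_is_left: bool = True,
) -> PreferenceTrial:
    """Markov dwell model standing in for scored video: a simulated event log.

    The female alternates between the neutral zone and side visits; visited
    sides are chosen with odds ``preference : 1`` for side1, dwell times are
    exponential with mean ``mean_dwell_s`` (scaled by the preference on the
    favored side), and within a visit she steps middle -> speaker -> fence
    with zone-specific dwells.  ``preference = 1`` is the no-preference null.
    """
    rng = np.random.default_rng(seed)
    rows = []
    t = float(rng.uniform(5.0, 20.0))  # initial neutral dwell
    p1 = preference / (preference + 1.0)
    while t < TRIAL_LENGTH_S - 1.0:
        side = "side1" if rng.random() < p1 else "side2"
        scale = mean_dwell_s * (preference if side == "side1" else 1.0) / ((preference + 1) / 2)
        depth = rng.integers(1, 4)  # how deep the visit goes
        for zone in ("middle", "speaker", "fence")[:depth]:
            if t >= TRIAL_LENGTH_S:
                break
            rows.append({"time_s": round(t, 2), "zone": zone, "side": side})
            t += rng.exponential(scale / 3.0) + 0.5
        if t >= TRIAL_LENGTH_S:
            break
        rows.append({"time_s": round(t, 2), "zone": "neutral", "side": ""})
        t += rng.exponential(8.0) + 0.5
    events = pd.DataFrame(rows, columns=["time_s", "zone", "side"])
    events = events[events["time_s"] <= TRIAL_LENGTH_S]
    return PreferenceTrial(
        female_id=female_id,
        trial_id=trial_id,
        stimulus_side1=stimulus_side1,
        stimulus_side2=stimulus_side2,
        events=events,
        side1_is_left=side1_is_left,
    )
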