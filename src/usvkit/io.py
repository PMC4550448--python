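"""Readers and writers for the delimited text formats used by the pipeline.

Feature tables are one row per syllable (or per individual x syllable type
for pre-aggregated tables) with the canonical 24 spectral variable names
plus ``duration`` and identifier columns; the reader sniffs the delimiter
(tab, comma or semicolon) so exported spreadsheet tables load directly.
Event logs are ``trial_id, female_id, time_s, zone, side`` rows.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .playback import PreferenceTrial
from .simulate import FEATURE_COLUMNS

__all__ = [
    "read_feature_table",
    "write_feature_table",
    "read_event_logs",
    "read_group_table",
]


def _sniff_sep(path: Path) -> str:
    """Pick the delimiter that splits the first lines consistently."""
    with open(path, encoding="utf-8", errors="replace") as fh:
        lines = [fh.readline() for _ in range(3)]
    lines = [ln for ln in lines if ln.strip()]
    best, best_count = "\t", 0
    for cand in ("\t", ",", ";"):
        counts = {ln.count(cand) for ln in lines}
        if len(counts) == 1:
            (c,) = counts
            if c > best_count:
                best, best_count = cand, c
    return best


def read_feature_table(path, require_features: bool = True) -> pd.DataFrame:
    """Read a per-syllable or per-record feature table (delimited text)."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_sep(path))
    df.columns = [c.strip() for c in df.columns]
    if require_features:
        missing = [c for c in FEATURE_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"feature table {path} lacks columns: {missing}")
    return df


def write_feature_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_group_table(path) -> pd.DataFrame:
    """Individual -> population/subspecies/species membership table."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_sep(path))
    df.columns = [c.strip() for c in df.columns]
    if "individual" not in df.columns:
        raise ValueError("group table needs an 'individual' column")
    return df


def read_event_logs(path) -> list[PreferenceTrial]:
    """Read playback event logs into one PreferenceTrial per (female, trial).

    Expected columns: ``female_id, trial_id, stimulus_side1, stimulus_side2,
    time_s, zone, side`` (and optionally ``side1_is_left``).
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_sep(path))
    df.columns = [c.strip() for c in df.columns]
    needed = {"female_id", "trial_id", "time_s", "zone", "side"}
    missing = needed - set(df.columns)
    if missing:
        raise ValueError(f"event log {path} lacks columns: {sorted(missing)}")
    trials = []
    for (fem, tri), sub in df.groupby(["female_id", "trial_id"], sort=True):
        first = sub.iloc[0]
        trials.append(
            PreferenceTrial(
                female_id=str(fem),
                trial_id=str(tri),
                stimulus_side1=str(first.get("stimulus_side1", "side1")),
                stimulus_side2=str(first.get("stimulus_side2", "side2")),
                events=sub[["time_s", "zone", "side"]].reset_index(drop=True),
                side1_is_left=bool(first.get("side1_is_left", True)),
            )
        )
    return trials
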