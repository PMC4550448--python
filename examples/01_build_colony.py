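"""Build a synthetic colony and look at its vocalizing behavior.

Generates ten males for each of the eight default groups (four M.m.musculus
populations, M.m.domesticus, two hybrid lines, M.spicilegus) and prints the
per-group share of vocalizing males, median latency to the first call and
syllable output.  Vocalizer shares span roughly 29-87% and latencies are
heavily right-skewed, as in wild-derived colonies.
"""

import usvkit as uk

colony = uk.build_default_colony(seed=1, n_per_group=10)
summary = uk.colony_summary(colony)

per_group = summary.groupby("population").agg(
    males=("individual", "size"),
    vocalizers=("is_vocalizer", "sum"),
    median_latency_s=("latency_s", "median"),
    median_syllables=("n_syllables_30min", "median"),
)
print(per_group.round(1))
print(
    f"\n{per_group.vocalizers.sum()} of {per_group.males.sum()} males vocalized; "
    "latency medians range from seconds (eager populations) to >10 minutes."
)
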