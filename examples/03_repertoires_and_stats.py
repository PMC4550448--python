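"""Repertoires and the nonparametric comparison battery.

Summarizes each vocalizer's first 100 syllables into a repertoire (counts
per type, repertoire size 0-7), then runs the standard battery: a
chi-squared test of vocalizer proportions across groups, a Kruskal-Wallis
test of latencies, and per-type Kruskal-Wallis comparisons of repertoire
proportions with Benjamini-Hochberg correction.
"""

import numpy as np
import pandas as pd

import usvkit as uk

colony = uk.build_default_colony(seed=3, n_per_group=10)
summary = uk.colony_summary(colony)

# vocalizer proportions across the 8 groups
tab = summary.groupby("population")["is_vocalizer"].agg(["sum", "count"])
chi = uk.chi_square(np.c_[tab["sum"], tab["count"] - tab["sum"]])
print(f"vocalizer proportions: chi2 = {chi.statistic:.2f}, df = {chi.df:.0f}, "
      f"p = {chi.p:.4g}")

# latency comparison among vocalizers
lat = summary[summary.is_vocalizer]
groups = [g["latency_s"].to_numpy() for _, g in lat.groupby("population")]
kw = uk.kruskal_wallis(*groups)
print(f"latency across groups: H = {kw.statistic:.2f}, df = {kw.df}, p = {kw.p:.4g}")

# per-type repertoire proportions, BH-corrected
profiles = []
for ind in colony:
    if ind.is_vocalizer:
        prof = uk.build_repertoire(ind.id, [s.type for s in ind.syllables], cap=100)
        row = {"population": ind.group.name,
               "repertoire_size": prof.repertoire_size}
        row.update({t.value: p for t, p in prof.type_proportions.items()})
        profiles.append(row)
rep = pd.DataFrame(profiles)
print(f"\nmean repertoire size: {rep.repertoire_size.mean():.1f} of 7 types")

pvals, names = [], []
for t in uk.CANONICAL_TYPES:
    groups = [g[t.value].to_numpy() for _, g in rep.groupby("population")]
    if sum(g.size > 0 for g in groups) < 2:
        continue
    res = uk.kruskal_wallis(*groups)
    pvals.append(res.p)
    names.append(t.value)
adj = uk.fdr_adjust(pvals)
for name, p, q in zip(names, pvals, adj):
    flag = "*" if q < 0.05 else " "
    print(f"  {name:22s} p = {p:.4f}  BH-adjusted = {q:.4f} {flag}")
print("Starred types differ among groups after FDR control.")
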