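# Methods

This note documents the models, defaults and numerical choices behind
usvkit, and what the synthetic study conditions can and cannot demonstrate.

## Spectrogram and features

Spectrograms use a flat-top windowed STFT, FFT length 512, 50% overlap,
magnitudes in dB re full scale (a unit-amplitude sine reads ~0 dB). At the
250 kHz default rate this gives 488 Hz bins and 1.024 ms frame spacing. A
single configurable floor (default −90 dBFS) is applied before
segmentation; the original recording hardware's two-number noise-reduction
setting is not reproducible verbatim, so one floor stands in for it.

Segmentation marks a frame active when any bin exceeds the floor (+1 dB),
merges active runs separated by gaps shorter than `gap_ms` (default 10 ms,
below the smallest inter-syllable gap of 0.03 s) and drops runs shorter
than `min_dur_ms` (default 5 ms, well under typical 20–50 ms syllables).

Per syllable, four spectra are measured: the first frame (start), the frame
at index ⌊(n−1)/2⌋ (center; tie toward earlier), the last frame (end) and
the frame of maximum amplitude (max). Whether "start/end spectrum" means a
single frame or a short average is not standardized across tools;
single frames are used here. From each spectrum: peak frequency (argmax),
peak amplitude, min/max frequency at −20 dB relative to the peak
(configurable; the threshold is not standardized either), bandwidth
(= max − min exactly) and Wiener entropy (geometric/arithmetic mean ratio
of the linear power spectrum, bounded [0, 1]; a configurable normalized
Shannon alternative was considered unnecessary since Wiener entropy already
matches the tonal < 0.3 / noisy > 0.4 calibration). Duration completes the
25-variable vector (24 spectral + duration).

The contour used for typing is the per-frame argmax frequency, restricted
to frames within 25 dB of the syllable's loudest frame — at onset/offset
ramps the tone is too weak for the argmax to be meaningful and background
noise would otherwise inject spurious frequency jumps.

## Syllable typing

Decision order: (1) count adjacent-frame jumps ≥ 10 kHz — two jumps →
2-frequency-step, one → 1-frequency-step, three or more → unclassified;
(2) modulation (max − min of the smoothed contour) ≤ 2 kHz → constant;
(3) monotone rise ≥ 10 kHz → upsweep; (4) monotone fall ≥ 5 kHz →
downsweep; (5) single interior minimum/maximum with modulation ≥ 4 kHz →
U-shaped / chevron; (6) otherwise unclassified. Step detection precedes
shape rules so a stepped contour is never read as a sweep.

Numerical choices: the step threshold (10 kHz, at the upsweep-modulation
scale) is configurable; "continuous/monotone" is judged after a 3-frame
running median with a 1 kHz *cumulative* reversal tolerance — bounding the
cumulative reversal (excursion above the running minimum, or below the
running maximum) rather than per-step changes is essential, since a slow
U-turn would otherwise pass a per-step test. The seven published rules are
not exhaustive (e.g. a 3 kHz non-monotone wobble), so an explicit
Unclassified bucket exists; such syllables occupy first-100-window slots
but do not count toward repertoire size (configurable via the profile).

Repertoires use each male's first 100 syllables; repertoire size is the
number of distinct canonical types present (0–7).

## Synthetic colonies

Eight default groups (four *M.m.musculus* populations, *M.m.domesticus*,
two hybrid lines, *M.spicilegus*). Per group:

* **Vocalizer probability**: 0.87/0.39/0.31/0.86 for *M.m.m.1–4*, 0.29 for
  *M.m.d.* (printed values); 0.50/0.58 (hybrids) and 0.71 (*M.s.*) chosen
  once inside the observed 29–87% range.
* **Latency**: log-normal (σ_log = 1.1), truncated to the observed
  0.5–1437.5 s; medians 11/400/668/15 s for *M.m.m.1–4* (eager populations
  call within seconds), 300/100/250/150 s for the rest, consistent with the
  published ordering (*M.m.m.1* and *4* fastest).
* **Syllable count per 30 min**: negative binomial (dispersion 1.3),
  truncated to the observed 31–2661; means 256–1057 matching the printed
  population range. Sequences are materialized only up to 150 syllables per
  male (all per-syllable analyses use the first 100); the full count is
  kept for emission-rate statistics.
* **Repertoire weights**: 7-vectors with upsweeps dominant (0.44–0.70;
  group mean ≈ 56%), rare types (chevron, 2-frequency-step) at small or
  zero weight in the groups that lack them. Individual repertoires are
  Dirichlet-perturbed (concentration 50), so rare types are genuinely
  absent from some males.
* **Feature bases**: group means of pFmax / pAMPmax / entmax / duration.
  *M.s.* sits at the printed 74.69 kHz / −22.59 dB / 0.199 / 0.030 s; the
  *M.m.* populations are spread (±1.5 kHz, ±1 dB, ±0.007, ±1.5 ms) so that
  their record-weighted pool reproduces 69.75 kHz / −18.0 dB / 0.187 /
  0.0325 s. Note the entropy contrast follows the printed numbers
  (*M.s.* 0.199 > *M.m.* 0.187).
* **Inter-syllable gaps**: uniform on 0.03–0.94 s; frequency-step contours
  are zero-order-hold segments with a true instantaneous jump.
* **Tonality** (default 0.92 ± 0.03) maps inversely to additive broadband
  noise in the renderer, keeping rendered syllables in the tonal (< 0.3)
  entropy regime.

### Feature model and its calibration

The 24 spectral variables are generated blockwise as
mean(group, type, position) + individual "voice" + per-syllable noise, with
both random terms sharing a within-block correlation matrix: a 4×4 position
matrix for frequency (correlation a = 0.79 among end/center/max, c = 0.71
between start and the rest; min/max frequency are derived as
peak ∓ bandwidth/2, so the 12-variable block inherits it) and
equicorrelation for amplitude (0.745), bandwidth (0.15) and entropy
(0.515). These are *noise* correlations; the correlation a PCA sees also
contains the between-type/position/group mean structure, so the constants
were solved empirically such that the full pipeline (emit → individual×type
means → 12-outlier removal → per-block correlation PCA) reproduces the
canonical % variation row 79.47 / 9.34 / 83.19 / 42.31 / 65.59 under the
default conditions (measured 78–81 / 8.9–10.1 / 82–85 / 41–43 / 65–67
across seed batches).

The between- vs within-individual split is not published and had to be
chosen: voice SD = 0.7σ with per-syllable noise 2.77σ, making an
individual-mean record over a typical ~15-syllable type window have
variance ≈ σ². The moderate voice share matters: records of one male land
on both sides of any train/test split, and an overly distinctive voice
would let a flexible classifier recognize *males* rather than populations —
with a 90% voice share the 8-group SVM rate climbed far above the
published < 46% regime, while the chosen partition keeps both classifiers
under it without affecting species-level separation. Duration uses its own
log-scale partition (0.95/1.0 of σ_log, group σ_log 0.45 for *M.m.*, 0.23
for *M.s.*).

Type offsets are re-centered per group by *record* weights — the
Beta-binomial probability that each type appears in a male's
first-min(count, 100) window — so that group record-level means land on the
stated bases (published species means are quoted at the individual×type
record level). Residual centering error is ≤ ~0.15 kHz / 0.15 dB at large n.

### What the synthetic conditions do not show

The generator is Gaussian-within-block with linear/piecewise contours: no
harmonics, no vocal-tract filtering, no room acoustics, no non-stationary
background noise, no temporal syntax beyond i.i.d. type draws, and
rendered-entropy values depend on the spectrogram floor rather than on the
feature model's entropy block. Passing tests therefore demonstrate that the
*analysis chain* is correct and calibrated to the published summary
statistics — not that it would reach the same accuracy on real recordings,
whose nuisance structure is richer.

## Multivariate analysis

The record unit is the individual mean per syllable type over the first 100
syllables (up to 7 records per male); combined-type analyses pool these
records, which reproduces record counts larger than the number of males.
Outlier screening removes the k = 12 records with largest squared
Mahalanobis distance on standardized variables (pseudo-inverse fallback for
singular covariance; ties broken by record order). Block PCA retains 2
frequency axes and 1 axis per other block, orients each axis so its
largest-magnitude loading is positive, and reports loadings as
variable–component correlations.

SVM: RBF kernel in a standardized pipeline, γ and cost over powers of two
2⁻⁸…2⁴ (the published analysis names the tuned parameters but not the
grid), 10-fold CV on a stratified 80% training split (stratification
prevents empty test classes for 4-member groups), accuracy on the held-out
20%. DFA: Wilks' Λ = Π 1/(1+θᵢ) over the eigenvalues of W⁻¹B with Rao's F
approximation; classification by leave-one-out. Priors default to
*proportional* to group sizes: with the printed per-variable effect sizes
and the 289:54 record imbalance, proportional priors reproduce the
published ~87% species DFA rate while equal priors predict ~76%, so
proportional is taken as the convention the published rates reflect
(configurable to equal). MANOVA reuses the same Wilks/F machinery and is
cross-checked against statsmodels.

## Nonparametric battery

Two-sided p-values throughout. Mann-Whitney reports U = min(U₁,U₂), exact
enumeration when n₁n₂ ≤ 100 without ties, otherwise the tie-corrected
normal approximation without continuity correction. Wilcoxon signed-rank
drops zero differences and reports Z = (μ_W − W⁺)/σ_tie, negative when the
first sample dominates — the convention under which all published Z values
(preferred side with larger retention times) are negative; swapping samples
flips the sign and preserves p. Exact path for n ≤ 15 without tied
magnitudes. Kruskal-Wallis is tie-corrected; χ² is Pearson without
continuity correction (expected cells < 1 raise a warning flag, not an
error); the binomial test is exact two-sided; Levene centers on the mean;
Spearman as usual. FDR control is Benjamini-Hochberg (the commonly cited
variant). The mixed model for repeated playback measures is a REML
random-intercept fit (statsmodels MixedLM) with a Wald test of the fixed
slope, falling back to OLS (flagged) for single-trial or non-identifiable
cases. Latency comparisons include vocalizers only; non-vocalizers are
excluded, not censored.

Null calibration: every battery test's type-I error at α = 0.05 is checked
by simulation (2000 replicates) against the DKW band 0.05 ± 0.0304; the
exact binomial test is conservative by discreteness and is run at n = 100
where its achievable level stays inside the band.

## Playback analysis

Event logs (timestamped zone entries over a 310 s trial) are the input
unit; a two-state Markov dwell simulator stands in for scored video. The
Fence is a contact state scored as its own zone, mutually exclusive with
the Speaker zone; aggregates are cumulative (F ≤ F+S ≤ F+S+M). Zone credit
is exactly conservative (all credited time sums to 310 s). The latency of
a never-entered side is set to 310 s. Trials shorter than 310 s are
rejected, not rescaled. Playback plans standardize to 399 ± 3 syllables
with 1 s inter-phrase gaps and 0.03–0.94 s inter-syllable gaps;
segment layouts follow the published designs (ten 30 s segments for
10 contributors, four 76.5 s segments for 4, five 61 s repetitions for a
single male; other pool sizes split ~306 s evenly).

## Problem sizes

Test-suite and acceptance runs use: 20 study-composition colonies (~66
vocalizers, ~320 records each) for the species DFA rate; one such colony
for SVM runs; two 320-male colonies for the PCA row; a 1200-male colony for
species means (uncertainty is dominated by the individual voice, so means
are asserted within 3 standard errors computed from the data plus a small
centering margin); ~250 rendered syllables for the audio round trip; 2000
replicates per null calibration. These sizes keep every quantity's Monte
Carlo error comfortably below the tolerances while the full suite runs in
a few minutes.

## Known limitations

* Rendered-waveform entropy is floor-dependent and not numerically tied to
  the feature model's entropy block (the two paths share frequency,
  amplitude and duration structure).
* The contour-based typing of real, noisy recordings depends on the 25 dB
  contour gate and the 10 kHz step threshold; both are exposed as
  parameters and were chosen for the synthetic noise regime.
* Exact reproduction of the published per-dataset numbers (e.g. the
  deposited mean-data table's PCA row to two decimals, or the control
  experiments' exact Z values) requires the deposited per-record data; the
  package's readers accept such tables directly, and the synthetic
  surrogates check the same quantities at Monte Carlo precision.
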