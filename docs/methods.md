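# Methods

This package re-implements, as a tested pipeline over synthetic data, the
computational analysis used to map pioneer-factor (FoxA) occupancy at
transcriptionally silent genes from tiling-array ChIP-chip, and the
downstream statistics: motif enrichment in two dimensions, expression-based
activity classification, conservation profiling, and immunohistochemistry
staging tests.

## Peak calling

**Model.** Probe log-ratios from a competitive hybridization are treated as
signal plus symmetric noise. For each probe, the window spanning
`[mid − w/2, mid + w/2)` (default `w = 400` nt) collects the `n` member
probe values and is scored

    T = sqrt(n) · TM(x_1 … x_n)

where `TM` is the `trim_fraction`-trimmed mean (default 0.10; the
`floor(trim·n)` smallest and largest values are dropped, so `trim = 0`
gives the plain mean). The `sqrt(n)` factor makes noise-only window scores
share a common scale regardless of probe density; trimming robustifies
against single outlier probes. Windows with fewer than `min_probes = 5`
probes are discarded (sparse or masked regions).

**Empirical null.** Noise-only T-scores are symmetric around zero while
enrichment is one-sided, so the negative scores estimate the null: the
p-value of a positive score `T` is

    p(T) = (1 + #{|T_neg| ≥ T}) / (1 + M)

with `M` the total window count and add-one smoothing so `p` is never 0;
scores `T ≤ 0` get `p = 1`. Because the mirrored null is effectively
two-sided, positive-score p-values are uniform on
`(0, (1 + N_neg)/(1 + M)] ≈ (0, 0.5]` rather than `(0, 1)`; calibration
checks (`peaks.null_calibration`) therefore test uniformity over that
attainable range. The overall fraction of windows below a threshold
`alpha` still tracks `alpha` itself, which is what the detector's false
positive rate depends on. A consequence of the add-one estimator: no call
can be made at `alpha` unless `M > 1/alpha` (at the default
`alpha = 1e-4`, a track needs more than 10,000 windows).

**Merging and the either rule.** Windows with `p < alpha` are sorted and
merged whenever the inter-span gap is below `g` (default 100 nt); a merged
region carries the union span, the best member T and its p-value. Regions
are called independently for the ChIP-vs-IgG and ChIP-vs-input
comparisons and then unioned by coordinate overlap (≥ 1 bp); the output
records which comparisons contributed and keeps the smaller p.

**FDR from the control hybridization.** The identical single-track
pipeline is run on the IgG-vs-input control; FDR = control region count /
ChIP region count, clamped to [0, 1]. Note a systematic bias this
estimator inherits from the either rule: false calls accumulate over
*both* ChIP channels while the control contributes one channel, so the
estimate undershoots the truth-table false-call fraction by roughly the
number of ChIP comparisons unioned (measured factor ≈ 1.8 on synthetic
data). The benchmark accepts agreement within a factor of 2 for exactly
this reason.

## Motif enrichment

**Geometry.** For each called region the binding element is located as
the best PWM hit on either strand (ties to the smaller coordinate; below
threshold, the region midpoint with a fallback flag). Region A is the
500 nt centered on the element (foreground); X and Y are the outer 250-nt
flanks 250–500 nt from the element on each side, so the background has
the same total length per locus. A peak-centered variant (ignoring the
element position) is available through
`RegionSequenceSet.from_element_centered` by passing midpoint-centered
sequences.

**Scoring.** PWMs are count matrices converted to log2-odds with a 0.25
per-cell pseudocount against a uniform (configurable) background.
Scanning scores every offset on both strands; at one offset only the
higher-scoring strand is recorded. Non-ACGT bases contribute 0 — the
background expectation on the log-odds scale.

**Enrichment.** The unit is per-sequence presence/absence: with `k_fg` of
`n_fg` foreground units containing at least one hit and a background rate
`p0 = max(k_bg/n_bg, 0.5/(n_bg+1))` (floored so an empty background cannot
force p = 0), significance is the exact binomial upper tail
`P(Bin(n_fg, p0) ≥ k_fg)`. A hits-per-base variant is available
(`unit="site"`). Presence/absence keeps the binomial model exact and
length-robust, at the cost of ignoring multiple occurrences per locus.

**Threshold optimization.** Per motif, candidate thresholds are
`grid_size = 50` quantiles of the pooled per-unit best scores; the
threshold minimizing the binomial p wins, subject to at least
`min_hits = 3` foreground hits, with ties broken toward the stricter
threshold. Minimizing over a grid is a selection: even a motif with no
true class contrast attains optimized p-values well below 1 (typically
1e-3 to 0.2 on 30-vs-30 loci). Reported p-values are raw, matching how
such screens are usually plotted; an optional Benjamini–Hochberg column
corrects across motifs but not across the threshold grid. Rankings
between motifs remain meaningful because all motifs enjoy the same
selection; absolute dim2 p-values near the selection floor should not be
read as evidence.

**Two dimensions.** Dimension 1 contrasts region A (all loci) against the
X+Y flank units; dimension 2 contrasts A of silent-gene loci against A of
active-gene loci and vice versa, each with independently optimized
thresholds, reporting the direction with the smaller p. A class with
fewer than 3 loci flags dimension 2 unavailable.

## Activity classification and association

Relative expression is `2^−(Ct_gene − Ct_ref)` (reference: an HPRT-like
housekeeping gene). A gene is *weak/silent* when its expression is
strictly below `1e-4` of the albumin-analog gene in the same table; the
boundary value is active. Labels are invariant to common rescaling.
Regions are linked to the nearest TSS by absolute distance (signed
distance: midpoint − TSS, flipped for minus-strand genes; ties to the
lexicographically smaller name). Proximal binding (|distance| ≤ 5 kb) is
cross-tabulated against activity with a Haldane-corrected odds ratio.
Occupancy–activity correlation is Pearson by default (Spearman by flag);
the published analysis does not state the flavor. Array calls are
validated against locus ChIP-qPCR with a 2-fold-over-background
positivity rule; sensitivity/specificity follow the usual confusion-matrix
definitions, with NaN when a class is empty.

## Conservation profiles

A per-base conservation track (PhastCons-style scores in [0, 1], NaN for
missing) is averaged over fixed windows (±1000 nt, i.e. the 2-kb
extraction) around site centers; sites near chromosome edges are padded
as missing. The bound-vs-unbound contrast is the difference of grand
means with a 1000-replicate site-level percentile bootstrap 95% interval
(seeded). The bootstrap is added engineering — the original comparison
shows mean curves only — and the output labels it as such. Because called
regions are usually narrower than the 2-kb window, a rectangular
elevation confined to the region spans produces a grand-mean difference
smaller than the elevation; the benchmark therefore uses sites whose
elevated span fills the window when it checks recovery of the elevation
parameter.

## IHC staging statistics

Per sample: percent positive nuclei = 100 · stained/total. Per stage:
mean, SD (n−1), SEM. Contrasts between a reference stage and each other
stage use the two-sample *pooled-variance* Student t computed directly
from (mean, SD, n) — the form in which the published staging table
reports its data (SD recovered as SEM·√n) — with two-sided p. Pooled
variance is the default because it reproduces the published
normal-vs-Barrett's bound (p ≈ 0.119 ≤ 0.12); Welch's unequal-variance
variant (≈ 0.035 on the same rows) is available by flag. Zero pooled
variance yields t = 0, p = 1 for equal means and a flagged p → 0
otherwise.

## Synthetic data generator

The generator reproduces the statistical structure each stage consumes,
not the biology:

- **Probe tracks** — 50-nt probes every 24 bp (the array's geometry);
  value = N(0, `noise_sd`) + rectangular spike heights covering the probe
  midpoint in the spiked channels. `noise_sd = 0.5` log-ratio units, a
  typical two-color tiling-array noise scale; the default spike height is
  3× the noise SD. Gaussian i.i.d. noise matches the symmetric-null
  assumption the detector exploits; rectangular spikes make window-score
  expectations analytic. No probe GC/affinity bias, dye bias, or spatial
  artifacts are modeled — so passing benchmarks demonstrate correctness
  of the statistics, not robustness to real array artifacts.
- **Sequences** — 1000 nt per locus, i.i.d. background composition, one
  primary-motif instance sampled from the PWM within ±50 nt of the
  center, class-specific co-motifs (Bernoulli embed probability, default
  0.8) placed in the central 500 nt, placements recorded in a truth
  table. Built-in FoxA/Rfx/HNF4-like matrices are synthetic
  consensus-derived stand-ins, sharp enough that sampled instances score
  above the 95th percentile of background scores.
- **Conservation** — Beta(1, 9) baseline (mean 0.1, genome-typical) plus
  a constant elevation (default 0.4) inside bound regions, clipped at 1.
- **Expression** — Ct values constructed so `2^−ΔCt` reproduces target
  relative expressions exactly: 56 active genes (log-uniform on
  [1e-4, 10] of albumin, including the albumin analog at 1.0) and 30
  silent genes (log-uniform on [1e-9, 1e-5]), perfectly separable by the
  1e-4 rule by construction.
- **Nucleus counts** — per sample, total ~ UniformInt[300, 600]; a
  staining propensity ~ N(stage mean, stage SD) clipped to [0, 1];
  stained ~ Binomial(total, propensity). Stage parameters default to the
  published staging table (n = 5/11/6/20; 61.6/42.2/4.8/3.3 % positive;
  SD = SEM·√n).

**Randomness.** Every draw descends from one integer seed through a
single rule: component *X* uses
`default_rng(SeedSequence(seed, spawn_key=(crc32(X),)))`, so components
are independent, individually reproducible, and byte-identical across
runs with the same seed.

## Benchmark problem sizes

The benchmark experiments use a 2.4-Mb synthetic genome (≈ 1e5 probes and
windows), 50–86 spiked loci, 60 loci for the motif contrast (30 per
class), 20 replicate seeds for the stochastic checks, and a 20-matrix
library (planted motif + 19 random decoys). These sizes put ≈ 10
expected null windows past the detector threshold per track and give the
binomial contrasts double-digit counts per class — large enough for
stable rates, small enough to re-run routinely.

## Known limitations

- The T-score family (robust mean × √n) follows the cited
  sliding-window approach; the exact published statistic is not printed,
  so trimmed vs plain mean is configurable rather than fixed.
- The empirical null uses the raw mirrored tail; a normal fit to the
  negative scores is a reasonable alternative not enabled by default.
- The control-channel FDR estimator undershoots when two ChIP channels
  are unioned (see above).
- Optimized enrichment p-values are selection-biased (see above); the
  per-sequence presence/absence unit discards occurrence counts.
- Per-field staining percentages (multiple fields per sample) are not
  modeled; the per-sample percentage is the analysis unit.
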