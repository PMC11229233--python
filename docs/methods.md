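# Methods

This note documents the statistical model behind `promevol`, the
conventions the implementation fixes where the underlying method leaves
room, and what the synthetic benchmarks do and do not demonstrate.

## Coordinates and windows

All positions are signed offsets from the transcription start site in the
orientation of transcription: the TSS base is +1, the base immediately 5′
of it is −1, and offset 0 does not exist. The analysis window spans
`upstream` + `downstream` positions (default 1000 + 300) and contains a
promoter sub-interval (default −380..−31, i.e. the 350 nt upstream of the
canonical TATA-box position at −30). Sequences and conservation tracks are
re-oriented to the gene's transcription direction at ingest; everything
downstream of ingest is strand-agnostic.

## Event model

Given a multiple alignment whose first row is the reference species, each
non-reference species yields a binary event track over reference
positions:

* mismatched base → `base_change`;
* species gap at a reference base → `indel` (each deleted reference base
  is one event);
* insertion run in the species (gap in the reference) → a single `indel`
  event at the offset of the nearest 5′ reference base ("5′ anchoring");
  a leading insertion, which has no 5′ base, anchors to the first
  reference base. Window trimming keeps insertion columns with their
  anchor, so a boundary never splits the two;
* when both base-change and indel evidence land on one offset, the indel
  class wins (the event indicator is 1 either way);
* comparisons are case-insensitive; ambiguity or masked symbols (e.g. N)
  count as a change against a different symbol and as conserved against
  the same symbol.

The 5′-anchor rule and the one-event-per-insertion-run rule are
conventions of this package: they keep event tracks exactly
reference-length, which is what per-nucleotide heatmaps and the
promoter-window counting require.

## Sliding score and hotspot percentages

Per-position event counts (summed over species, optionally restricted to
base changes or indels) are smoothed with a centered 5-position mean,
truncated at the window ends (the mean is taken over the available
positions), giving the sliding event score *Se* at every window position.
The mean rather than the window sum keeps *Se* on the per-position event
scale; with the baseline computed by the same convention the hotspot
percentage is identical either way, only heatmap magnitudes differ.

The control baseline *Se^C* (or *p^C* for conservation scores) is the
arithmetic mean of all control values across all promoter-window
positions of all control genes, pooled. For genome-average baselines
(conservation mode) pooling across positions is the default; averaging
per gene first is a trivial variant the caller can compute with the same
primitives.

The hotspot percentage is a counting statistic over the promoter window:

* d = 100 · #{Se > Se^C} / N (strictly greater; ties never count),
* d^P = 100 · #{p < p^C} / N (strictly less),

with N the number of scored promoter positions — 350 at defaults, making
d and d^P bounded percentages and exactly symmetric constructions.
Conservation mode requires full promoter coverage; genes with any
reference-only position are removed upstream (with a logged reason), so
N never silently shrinks.

Group-level tracks: the concatenated-group convention sums event counts
across genes at each position. When groups of different sizes are
compared, the pipeline divides by the gene count so the group *Se* and the
control baseline sit on a common per-gene scale; with equal group sizes
the two conventions give identical comparisons. Group-level d^P pools
exceedance counts over the group's genes (N = 350 × group size).

## Significance testing

A gene or group is tested against the control with a Pearson chi-squared
test (df = 1, no continuity correction — counts are in the hundreds) on
the 2×2 table of exceed/non-exceed counts, each side contributing its own
N. A zero margin flags the comparison undefined (p = 1) rather than
raising. Correction is an explicit parameter: Bonferroni for small fixed
group panels, BH-FDR for gene-level panels; significance is corrected
p ≤ 0.05.

**Calibration caveat.** The chi-squared construction treats per-position
exceedance indicators as exchangeable counts. That holds for the
conservation statistic d^P when per-base scores are independent — the
synthetic conservation generator draws iid scores, and the null rejection
rate measured by the test suite and `scripts/acceptance.py` sits at the
nominal 5% level. It does **not** hold for the alignment statistic d at
sliding-window size 5: neighbouring indicators share 4 of their 5
underlying positions, the indicator autocorrelation inflates the variance
of the exceedance count several-fold, and the test rejects well above the
nominal level for near-null comparisons (the acceptance suite measures
roughly 0.3 at nominal 0.05 under identical simulated rates; multi-base
deletion runs alone keep it above nominal even at window size 1). This is
intrinsic to the smoothed-exceedance statistic itself, not to this
implementation. Consequence: alignment-mode chi-squared calls are
trustworthy for large effects (a 3× promoter rate increase is detected in
every replicate) but near-null alignment-mode significance should be read
as descriptive, not as a calibrated p-value. d^P-based tests, which the
genome-scale comparisons rely on, do not suffer from this.

## Expression stage

Germline/soma classification applies strict threshold filters to a
germline-vs-soma sorted-cell DE contrast plus three RPKM datasets:
germline ⇔ log2FC > 2 ∧ padj < 0.01 ∧ ovary RPKM > 10 ∧ embryo(0–2 h)
RPKM > 9; soma ⇔ log2FC < −1 ∧ padj < 0.01 ∧ ovary RPKM > 10 ∧ OSC
RPKM > 20 ∧ embryo RPKM < 2. The filter sets are disjoint by construction
(the fold change cannot satisfy both), so no gene gets two labels; every
pass/fail is recorded per gene.

Cross-species DE fits, per 1:1 ortholog pair, a negative binomial GLM
with a species indicator and an offset combining (a) median-of-ratios
sample size factors computed on the combined ortholog count matrix and
(b) per-gene, per-species length factors L_{g,s} / √(L_{g,A}·L_{g,B}).
The Wald test on the species coefficient gives p; BH across genes gives
padj; positive log2FC means higher expression in species A. Multiplying
one species' lengths by a constant c shifts every log2FC by exactly
−log2 c (toward the other species); this is exact because dispersions are
estimated on size-factor-normalized counts only — the length factor is
constant within a species and must not leak annotation divergence into
the replicate-variability estimate.

Dispersion: per-gene method-of-moments within species groups, shrunk on
the log scale (weight 0.7) toward a parametric trend α(μ) = a0 + a1/μ fit
across genes; genes with non-positive moment estimates take the trend
value; results clipped to [1e-8, 10]. A `dispersions` argument allows
substituting externally estimated values, which is how the test suite
cross-checks the engine against an established NB-DE implementation
(log2FC agreement r > 0.999 on equal-length data).

Volcano significance uses strict |log2FC| > 0.5 and padj < 10^−0.5
(≈ 0.316). The unusually permissive adjusted-p default mirrors a
log10(padj) < −0.5 plotting rule; it is a configurable parameter
(`padj_thresh`), deliberately not hard-coded. Promoter-score binning
groups genes by d^P into (25, 50], (50, 75] and (75, 100] (left-open:
d^P = 25 falls in no bin) and compares germline vs soma significant
fractions per bin and fold-change direction with chi-squared + BH-FDR
across bins.

## MKT stage

Standard MKT only: NI = (Pn/Ps)/(Dn/Ds), α = 1 − NI, two-sided Fisher's
exact test on [[Dn, Ds], [Pn, Ps]], BH-FDR per population, positive
selection ⇔ corrected p ≤ 0.05 ∧ α > 0 (the direction check keeps
significant *deficits* of nonsynonymous divergence from being called
adaptive). NI/α are flagged undefined when a needed denominator is zero;
the Fisher p is still reported. No Jukes–Cantor or low-frequency-
polymorphism corrections. Group-level calls are emitted both as pooled
count tables and as per-gene significant counts, since either summary may
be wanted. Note α is invariant under scaling all four counts; the Fisher
p is not. The per-gene α ratio estimator carries a Jensen bias of about
−(1/E[Dn] + 1/E[Ps]); the synthetic table means (Dn ≈ 60, Ps ≈ 120) are
chosen so this bias stays well inside the ±0.05 neutrality tolerance.

## Synthetic data: what it does and does not emulate

The generators are pure functions of a seeded config. Alignments use a
star phylogeny — each of the four non-reference lineages evolves
independently from the reference — with per-site Bernoulli substitutions
(always to a different base, so the per-site event probability equals the
rate), Bernoulli-start indels with geometric lengths (mean 2), and
region-specific rates (default 0.08 substitutions, 0.01 deletions, 0.01
insertions per site per branch, roughly the divergence scale of closely
related species pairs; fast-promoter genes multiply promoter rates by 3).
Conservation tracks are iid N(1, 1) scores with a promoter-mean shift of
−1 for fast genes. Counts are NB with log-normal gene means (median 150),
dispersion 0.05, ±30% library sizes, n = 4 per species, 10% DE genes at
|log2FC| = 2, and log-normal (σ = 0.1) length divergence. MKT tables are
Poisson with a shared nonsynonymous/synonymous odds of 0.3; the positive
regime inflates the Dn mean 3× (expected pooled α = 2/3).

None of this emulates real promoter biology: no phylogenetic tree
structure, no mutational spectra, no spatial autocorrelation of
conservation scores, no selection on sequences. Passing benchmarks
therefore demonstrates that the *statistics are computed correctly and
behave as designed under their own assumptions* — not that the biological
conclusions of any particular dataset are reproduced. In particular, real
PhyloP tracks are spatially autocorrelated, so real-data d^P chi-squared
tests inherit (in milder form) the calibration caveat described above.

## Numerical and degenerate-input choices

* Strict inequalities everywhere ties could arise (d, d^P, volcano
  thresholds, classification filters).
* Sliding-window means are ratios of integer-valued convolutions, so they
  are exactly reproducible and exactly comparable against naive loops.
* Zero-margin contingency tables and zero MKT denominators return flagged
  results, never exceptions; empty control groups, empty gene groups,
  ragged alignments and non-1:1 ortholog maps raise typed errors.
* Every removal rule (species coverage, window coverage, conservation
  coverage, multi-group membership, all-zero genes, non-1:1 orthologs)
  writes one row to an exclusion log; reported + excluded = input genes.
* All randomness flows through per-generator seed streams, so outputs are
  byte-identical for a given config regardless of call order.

## Problem sizes

Defaults used by the test suite and `scripts/acceptance.py`: 12 genes per
group and 100 (tests) / 50 (script) replicates for alignment-mode power
and specificity; 1000 replicates × 10 genes per group for chi-squared
calibration; 1000 genes × 4+4 samples for DE recovery and null
uniformity; 1000 genes for MKT regimes. These sizes put Monte-Carlo error
comfortably inside the asserted tolerances while keeping a full run in
the low minutes on one CPU.
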