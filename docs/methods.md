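# Methods

`tadrewire` integrates two-condition Hi-C contact maps, CTCF and ATAC peak
sets, gene models and RNA-seq counts to nominate genes whose expression
change co-occurs with a CTCF-supported TAD-boundary alteration, and to
classify each candidate enhancer–gene pair under an intra-TAD loop-alteration
model (mechanism 1) or an inter-TAD reorganization model (mechanism 2).
This note records the models, the parameters that matter, the numerical
choices, and what the synthetic-data tests do and do not demonstrate.

## Contact maps

Binned cis counts are held dense per chromosome (symmetric); trans counts as
sparse pair dictionaries. Raw counts are used as-is — matrix balancing is
assumed done upstream or absent; the directionality-index and compartment
statistics below are scale-invariant, so a global scaling of counts does not
change any call. Input is the HiC-Pro triplet format (`binA binB count`,
1-based ids) with its companion bins BED. Smoothing replaces each entry by
the mean of the (2h+1)×(2h+1) window, truncated at the matrix edges (the
mean is over the cells actually present); h = 0 is the identity.

## TAD calling

For bin *i* with upstream flank contact sum *A* (bins [i−w, i)) and
downstream sum *B* ((i, i+w]), with flanks truncated at chromosome ends:

    E  = (A + B) / 2
    DI = sign(B − A) · [ (A − E)² / E + (B − E)² / E ],   DI = 0 if A = B.

The flank window is 2 Mb by default (`di_window_bp`), the classical choice
at 40-kb resolution. Boundary calling uses a deterministic run-based
automaton rather than an HMM: bins are labeled downstream-biased
(DI ≥ t), upstream-biased (DI ≤ −t) or neutral, with
t = `t_sd` × SD(nonzero DI on that chromosome) and `t_sd` = 0.5 by default.
A TAD opens at the first bin of a downstream-biased run and closes at the
last bin of the next upstream-biased run; TADs shorter than
`min_tad_size_bins` (3 bins = 120 kb; an optional 5-bin setting matches the
usual 200 kb lower bound for mammalian TADs) are discarded. The automaton
is reproducible, parameter-light and directly testable against planted
truth; its trade-off is reduced sensitivity to weak boundaries (no evidence
pooling across bins), and DI is biased wherever a flank is truncated, i.e.
within `di_window_bp` of a chromosome end.

Boundaries are the bins at TAD starts and TAD last bins; two TADs meeting
at a junction contribute a single boundary bin. Cross-condition comparison
greedily matches nearest boundaries within ±1 bin (each matched once;
candidate pairs taken in (distance, position) order, which makes the match
deterministic and its size symmetric). Reorganization typing: a condition-1
TAD reciprocally covered (≥ 80% both ways) by the union of ≥ 2 condition-2
TADs with a gained boundary strictly inside it is a **separation**; the
mirror case with a lost boundary is a **fusion**; leftover unmatched
boundaries re-matched at ≤ 5 bins with displacement > 1 bin are **shifts**.
Swapping the two conditions maps fusion↔separation and preserves shifts.

## A/B compartments

At 100-kb resolution, per chromosome: smooth (h = 1), divide by the mean
contact at each distance (O/E), compute the Pearson correlation matrix over
bins with nonzero coverage with the main diagonal excluded, and take the
eigenvector of the largest-magnitude eigenvalue (dense symmetric
eigendecomposition; matrices are at most a few thousand square). The
eigenvector sign is arbitrary, so it is oriented so that positive-score
bins have the higher mean gene density (TSS count per bin; GC content is
the alternative basis). A = positive score, B = negative, NA = uncovered.
TADs are assigned the compartment of the mean eigenvector score over the
100-kb bins they overlap (bp intersection; an exact zero mean is NA).
Chromosomes with fewer than 3 covered bins, or a constant matrix whose
correlation is undefined, yield all-NA tracks with a warning.

## Significant interactions

At 10-kb resolution, cis bin pairs at distance ≥ 2 bins (adjacent bins are
excluded as self-ligation-dominated) are tested against an equal-occupancy
distance-stratified background: distances are grouped into up to 100 strata
with approximately equal numbers of possible pairs; within a stratum the
per-read contact probability is p_d = (stratum count sum) / (stratum pair
count × N_cis); each pair with count ≥ 1 gets an upper-tail
Binomial(N_cis, p_d) p-value at its observed count. This is the standard
binomial simplification of spline-refined distance models — adequate here
because only the threshold behaviour (count, p, q) is consumed downstream.
Trans pairs use the single uniform expectation p_t = 1 / (number of
possible inter-chromosomal bin pairs). Benjamini–Hochberg q-values are
computed over the tested pairs (count ≥ 1; zero-count pairs still inform
the stratum totals — this choice changes the BH denominator and is
deliberate). A call is retained iff read count ≥ 3, p ≤ 0.01 and q ≤ 0.01
jointly; output is sorted by read count descending. Upper binomial tails
are conservative when expected counts are small (the p-value support is
discrete); calibration statements therefore apply in the near-continuous
regime (expected counts ≳ 15).

## Expression

TMM scaling factors follow the trimmed-mean-of-M-values construction: the
reference sample is the one whose upper quartile of scaled counts is
closest to the mean upper quartile; per sample, genes zero in either sample
are dropped, log-ratios M and abundances A are rank-trimmed (30% per M
tail, 5% per A tail), and the factor is 2 to the inverse-variance-weighted
mean M, with the factor vector rescaled to geometric mean exactly 1. RPKM
uses the TMM-adjusted effective library size: count × 10⁹ / (effective
library × exonic length), with exonic length the union of a gene's exons.
Genes with RPKM below 1 in **at least one** sample are flagged
low-abundance and excluded from differential calling (taken literally;
note this removes genuinely on/off genes — an "in all samples" alternative
is available via the threshold configuration).

Differential calling uses a negative-binomial conditional exact test at a
fixed dispersion (0.1 by default): with one library (or a pooled sum of
replicates) per condition there is no replicate structure from which to
estimate tagwise dispersions, so a fixed value stands in for the usual
empirical-Bayes machinery. For a gene with counts (y₁, y₂) and effective
library sizes (N₁, N₂), the common abundance is (y₁+y₂)/(N₁+N₂); the
two-sided p-value sums, over all splits of the observed total, the
conditional NB probabilities no larger than the observed one. On identical
data this reproduces edgeR's fixed-dispersion `exactTest` decisions
exactly (cross-checked in the test suite). A gene is flagged up/down iff
BH-FDR < 0.05 and linear fold change ≥ 2 (or ≤ 0.5).

## Candidate-pair classification

* **Step 1 — events.** A boundary gained in condition 2 becomes an event
  iff some condition-2 CTCF peak overlaps the boundary bin ± 40 kb and no
  condition-1 peak does (presence/absence overlap only: the two CTCF sets
  are typically from different sources and not quantitatively comparable);
  lost boundaries mirror the rule. Boundary position is reported as the
  bin midpoint.
* **Step 2 — candidate genes.** Differentially expressed, promoter
  (TSS ± 2 kb) overlapping an ATAC peak in **both** conditions, and within
  1 Mb of some event. ("Consistent promoter accessibility" is read as
  *retained*, consistent with the both-conditions accessibility criterion.)
* **Step 3 — pairs.** Enhancer candidates are ATAC peaks accessible in both
  conditions (condition-1 peaks overlapping a condition-2 peak) that are
  promoter-distal. Distance is absolute peak-midpoint-to-TSS (a
  strand-aware upstream-only variant is a configuration switch; validated
  enhancers in this class of study are frequently downstream despite
  "upstream" phrasing). Mechanism 1 requires distance < 20 kb and an
  event boundary between peak and TSS; mechanism 2 requires distance
  < 100 kb and peak/TSS TAD co-membership in exactly one condition, with
  an event of the geometry-implied change between them. Because called
  boundaries are only bin-accurate (±1 bin is inherent to DI calling)
  while mechanism-1 spans are sub-bin, the between test expands the
  peak–TSS interval by one bin (`boundary_slack_bp`, default = the
  resolution).
* **Direction rules** ship as two named presets, because the two natural
  readings of the mechanism descriptions conflict: `printed` (default —
  mechanism 1: boundary gain → deactivation, loss → activation; mechanism
  2: gain → activation, loss → deactivation) and `worked_example`
  (mechanism 2 reversed, matching the fusion → activation geometry of the
  canonical fused-locus example). A gene up-regulated in condition 2 is
  labeled an oncogene candidate, down-regulated a suppressor candidate —
  a bookkeeping convention, not a biological claim.

Emission is deterministic: one pair per (gene, peak, mechanism) with the
event nearest the TSS, sorted by (gene, distance); output is invariant to
input ordering, and swapping the two conditions flips gained↔lost,
activation↔deactivation and oncogene↔suppressor.

## Synthetic data

The simulator generates the study conditions every recovery test runs
under. Contact maps: expected count ∝ (|i−j|+1)^(−1) × 3^[same TAD],
Poisson counts, 2 chromosomes × 20 Mb at 40-kb bins with 10⁵ cis pairs per
chromosome; nominal TADs are 20 bins (800 kb), so separation halves
(400 kb) sit mid-range for mammalian TADs and their boundaries remain
callable at this depth. The condition-2 layout applies planted fusion /
separation / shift events to the condition-1 grid. Event loci that carry a
planted gene are placed outside the 2-Mb DI flank-truncation zone (where
the index is biased by construction); gene-free stress events do use edge
loci. CTCF peaks sit at every boundary midpoint, present exactly in the
conditions where the boundary exists; ATAC promoter peaks exist in both
conditions for every gene; enhancer peaks sit at the planted offsets.
RNA counts are NB (dispersion 0.1) around a 400-count baseline summed over
two library replicates per condition; planted changes are 10-fold — with
single-condition libraries at this dispersion an order-of-magnitude effect
is what makes the planted truth statistically unambiguous rather than
seed-marginal.

Planted pairs: two of each (mechanism × change) combination, with
expression signs following the `printed` preset. Decoys violate exactly
one criterion each — distance, accessibility (enhancer present in one
ATAC set), DEG status, or direction — so a classifier failure localizes
the broken rule. Direction decoys are planted at inter-TAD distances: at
intra-TAD distances every (change, sign) combination legitimately
satisfies one of the two mechanisms' rule tables, so a "wrong direction"
decoy is only well-defined where the mechanism-1 distance gate also fails.

What passing these tests does **not** show: the generator has no
fragment-level structure, no coverage biases (GC, mappability), no
balancing artifacts, sharp block boundaries instead of gradual insulation
changes, identical peak coordinates across conditions, and no replicate
variability beyond NB noise. Recovery rates on real data will be lower and
depend on sequencing depth and the unknown true dispersion; the planted
scenarios establish correctness of the machinery, not field performance.

## Numerical choices and degenerate inputs

* DI is exactly 0 where A + B = 0; all-zero-DI chromosomes yield no TADs,
  with a warning.
* Equal-count flanks give DI = 0 by the sign convention (sign(0) = 0).
* BH q-values are computed with a stable sort; permuting the input order
  permutes the output identically.
* Compartment label ties (mean score exactly 0 for a TAD) are NA, never
  silently A or B.
* The exact NB test handles y₁ + y₂ = 0 as p = 1; the enumeration is over
  the conditional support (totals at desk scale are a few thousand at
  most).
* All randomness flows from `numpy.random.default_rng` seeded explicitly;
  identical (spec, seed) reproduce byte-identical simulator output.

## Problem sizes used in the shipped tests

The default planted scenario is 2 × 20 Mb at 40-kb bins (500 bins per
chromosome, 10⁵ cis pairs each), 24 planted events, 58 genes; the
compartment checkerboard is 200 bins at 100 kb; the calibration null is
145 bins at 10 kb with 2 × 10⁶ reads over ~10⁴ tested pairs; the DEG
simulation is 1050 genes. These sizes keep every property estimable (≥ 10⁴
pairs for calibration, ~100 boundaries for recovery rates) while the whole
suite runs in well under a minute.

## Known limitations

* The boundary automaton under-calls weak sub-threshold boundaries that an
  HMM pooling evidence across bins might recover.
* Compartment calls on translocated or highly aneuploid genomes inherit
  all the usual caveats of correlation-eigenvector methods; no
  sub-compartment resolution is attempted.
* The interaction caller does not model coverage heterogeneity between
  bins (no per-bin bias vector); with unbalanced input, hot bins inflate
  their pairs' significance.
* Candidate classification is a filter, not a statistical model: it emits
  every pair satisfying the criteria and attaches no confidence score
  beyond the underlying DEG FDR.
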