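# Methods

This note documents the models, parameter choices and numerical
conventions behind `epirewire`, and what the synthetic-data generator does
and does not emulate.

## Coordinates and interval semantics

All coordinates are 0-based, half-open (`[start, end)`), the native BED
convention.  Overlap means ≥ 1 shared base: abutting intervals such as
`[0,10)` and `[10,20)` do not overlap.  Overlap counting uses the sorted
arrays identity `#overlapping [s,e) = #(start < e) − #(end ≤ s)`, which
holds for arbitrary interval collections; it is validated against
quadratic brute-force scans in the test suite.  The distance from a point
(TSS) to an interval is 0 inside the interval, otherwise the gap to the
nearest covered base (`end − 1` on the right); ties between equidistant
features break toward the smaller coordinate.  Distance bins for
peak-to-TSS annotation are `[0, 5 kb)` proximal, `[5 kb, 40 kb]` distal,
`(40 kb, ∞]` none — the bin edges are conventions (inclusive-left) since
only "<5 kb / 5–40 kb / >40 kb" labels are standard.

Promoter windows are strand-aware: for a `+` TSS, `[tss−up, tss+down)`;
mirrored for `−`; clipped to chromosome bounds.  Two widths are used in
the field and both are exposed: 2 kb upstream for peak-to-promoter
overlap questions, and TSS ± 2 kb for promoter signal quantification
(`cluster_flank`).  They are deliberately not reconciled.

## Signal quantification

Coverage arrives as interval+value records (bedGraph).  For a region,
`raw = Σ value × overlap_bp` (a prefix-sum integral), then
`normalized = raw × 10⁶ / library_size / region_length_kb` with
`library_size = Σ value × width` over the whole track, and `log2(x+1)`
for the log scale.  This signal-per-million-per-kb + log2 convention is a
package choice; nothing downstream depends on its absolute scale.
Replicates are averaged **after** normalization and log transform (not
pooled), so replicate-level QC remains possible; composite profiles
likewise average replicate profiles.  Composite (metagene) profiles use
±5 kb flanks in 100-bp bins by default, flip the bin order for `−`-strand
anchors so +x is always downstream, and average within strata.

Expression strata follow the printed convention top 20% / (20–80]% /
bottom 10%; the (80–90]% band is labeled `unassigned` rather than
silently reassigned, because the three named strata do not tile.

Methylation at a region is the unweighted mean CpG beta
(`meth_reads/total_reads`), requiring ≥ 3 CpGs (guards sparse
RRBS-like coverage); with uniform read depth this equals read pooling.

## Differential calling

One statistical engine serves transcripts (counts) and peaks (raw signal
integrals, which are count-like):

1. **Size factors**: median-of-ratios against the per-feature geometric
   mean, computed on all-positive features (column-total fallback).
2. **Common dispersion** α: method of moments pooled across features.
   Within a group, `E[var(q)] ≈ mean(1/s)·m + α·m²` for normalized counts
   with mean m; α is the pooled mean of per-feature ratios
   `(v − m·mean(1/s))/m²` over adequately expressed features.  A median
   would be biased far low here: with two replicates the per-feature
   sampling distribution is χ²(1)-like and its median is well under its
   mean.  A common (not per-feature) α is the only identifiable choice at
   two replicates per state.
3. **NB score test**: under the null the common rate solves
   `Σ (y_j − s_jλ)/(1 + α s_j λ) = 0` (Newton iterations from the moment
   start).  Solving this exactly — rather than using the moment
   estimator — makes the intercept score vanish, which in turn makes the
   test *exactly* invariant to swapping the state labels (log2FC negates,
   p unchanged; a tested invariant).  The score statistic is `U²/I` with
   the information adjusted for the intercept; p from χ²(1).
4. **Labels**: BH FDR across all features; correlated ⇔ FDR < α and
   log2FC > τ (defaults α = 0.05, τ = 1); log2FC uses normalized means
   with a 0.5 pseudocount.

Peaks tested are the ≥1 bp-overlap merge of the high-state and low-state
peak calls, so features present in either state are covered.  Peak
ranking ("magnitude of change") is |log2FC| of the tested signal, ties by
smaller p then id; bins from `np.array_split` differ in size by ≤ 1.

Calibration (tested): at the generator's expression conditions — 4-fold
planted effects, mean 200, dispersion 0.05, n = 2 vs 2 — power ≥ 95%; on
null data the significant fraction stays within binomial noise of zero.

## Promoter chromatin clustering

Five promoter marks; vectors taken in the state where the transcript is
more lowly expressed (low state for correlated, high state for
anticorrelated transcripts), as log2 normalized signal in TSS ± 2 kb,
replicate-averaged.  The pipeline:

* **Presence calls**: per mark, a 2-component 1-D Gaussian mixture;
  presence = posterior of the upper component > 0.5.  Degenerate fits
  fall back to a median split.  "Degenerate" means components collapsed
  (means within 0.25) or a sub-5% component that is *also* unseparated
  (< 2 pooled SDs) — a small but well-separated minority mode is a real
  presence class, and treating it as degenerate would let the median
  split mislabel half the transcripts.
* **Seeding**: Ward-linkage agglomerative clustering on z-scored signal,
  cut at `k_init = 8` (> 4 so mixed groups can be discarded, not
  force-labeled).  Deterministic given the input.
* **Curation** mechanizes the expert-in-the-loop step so the pipeline is
  reproducible: each seed group is matched to the prototype of its
  majority presence pattern; members individually consistent with that
  prototype become training rows; groups under 80% agreement contribute
  nothing.  Prototype matching checks the repressed class first (its
  H3K4 marks are don't-care), then fully-active, then the two partial
  classes; this precedence makes the four patterns mutually exclusive.
  A user-supplied label file can replace curation entirely.
* **Classification**: L2-regularized multinomial logistic regression
  (C = 1) on z-scored continuous signal (binarization is used only for
  curation).  A call is unambiguous when the top posterior ≥ `p_min`
  (0.5) and beats the runner-up by ≥ `margin` (0.1); the rule itself is a
  package convention.  Assignments are invariant to transcript order.

Per-cluster mark-change summaries are means of (low − high) log2 signal
over unambiguous members with a seeded bootstrap percentile CI (1,000
resamples).

## Overlap enrichment

The counting unit is the **universe element** (any-overlap membership),
not base pairs.  The default universe is the ≥1 bp-overlap merge of the
query and all database sets; a user universe is used verbatim (after
sort/merge).  Per database set the 2×2 table is Fisher-tested
(two-sided by default; one-sided available), the odds ratio gets a +0.5
Haldane–Anscombe correction only when a cell is zero (never the p-value),
BH FDR is applied within each query's family, and results rank by
ascending p, then descending OR, then name.  Fisher p-values are verified
against direct hypergeometric tail summation for universes up to 500.

Gene-set enrichment restricts counts to the background and runs under
three schemes per (cluster, direction): all tested genes; the other three
clusters of the same direction; the same cluster with the opposite
direction (direction-specific enrichment within a chromatin class).

## Super-enhancers

Stitching merges peaks whose gaps are ≤ 12.5 kb (transitively, per
chromosome); optional TSS exclusion removes peaks fully inside TSS
± 2.5 kb windows before stitching (off by default).  Stitched enhancers
are ranked by summed normalized member-peak signal in the high state.
The hockey-stick cutoff scales rank and signal each to [0, 1] and cuts at
the point *farthest below the diagonal* (argmin of scaled signal −
scaled rank), the tangent-slope-1 point of a convex profile; ties within
float tolerance resolve to the highest rank, so an elbow-free profile
(linear ramp, constant signal) yields a cutoff at the maximum and no
supers.  Supers have signal strictly above the cutoff.  The cutoff is
invariant to uniform signal scaling.  Nearest-gene annotation uses the
point-to-interval distance with the smaller-coordinate tie rule.

Knockdown dynamics per super-enhancer: *widespread loss* when ≥ 75% of
member peaks are correlated, *localized change* when ≥ 1 but < 75%,
*stable* otherwise; the 75% threshold is a documented heuristic, not a
literature constant.

## Cell-type specificity

"Open in a cell type" = ≥ 1 bp overlap with that cell type's region set
(the panel arrives pre-thresholded as BED).  Per peak,
`share = n_open / K`; `exclusive_to_matched` requires exactly one open
cell type and that it is the matched one.  Exclusivity between two peak
subsets is a two-sided Fisher test.  Q-Q tables pair the 1st–99th
percentiles with linear (type-7) interpolation.

## Synthetic-data generator

The generator emulates the *structures* the analyses consume, not
sequencing reads.  Default study: 5 × 10 Mb genome, 2,000 transcripts,
4,000 H3K27ac peaks, 40 super-enhancer agglomerates (8–14 peaks each),
12-cell-type panel with one matched cell type, 2 replicates × 2 states.

* Tracks are per-peak/promoter rectangles on a 0.1 background,
  overlap-resolved by maximum; a present mark's log2 level draws from
  `Normal(6, σ)`, an absent mark's from `Normal(1, σ)`, independently per
  replicate (σ default 1.0).  Promoter mark patterns follow the planted
  prototype in the clustered state and the fully-active pattern in the
  other state; the repressed class's H3K4 marks are Bernoulli(0.5).
* Expression counts are negative binomial (dispersion 0.05, lognormal
  base means around 200) with symmetric ±1 log2 shifts per state for
  regulated transcripts (4-fold total) and per-sample depth factors in
  [0.85, 1.15].
* Peak fold changes are `±(1.1 + Gamma(1.5, 1))`; promoter co-location
  probability falls from 62% to 10% across the correlated magnitude
  ranking (flat 6% for anticorrelated), emulating the published gradient
  as generator *parameters*, never as reproduced counts.  Promoter peaks
  are hosted only at promoters whose H3K27ac is planted present in the
  clustered state (class-1 regulated or unregulated transcripts): a
  promoter acetylation peak cannot sit where the mark is absent, and
  hosting it there would corrupt the planted prototype signatures.
* TF sites land on 80% of top-decile correlated peaks, 12% of other
  correlated, 1% of anticorrelated, 2% of unchanged peaks (≈ 20% of all
  correlated peaks overall).  Methylation betas are Beta(2,8) at TF-bound
  peaks and Beta(8,2) elsewhere.  Panel openness probability decreases
  with correlated-peak magnitude; matched-exclusivity is forced at rate
  0.37 on top-decile TF-bound correlated peaks and also arises naturally
  when all other cell types happen to be closed, so the realized
  exclusive fraction is a mixture, not the forced rate alone.
* Layout: shuffled units (4.2-kb promoter blocks, compact super-enhancer
  agglomerates, 1–3-peak typical groups separated by > 12.5 kb trailing
  gaps) are packed sequentially per chromosome; infeasible configurations
  raise.  The null variant keeps the same geometry but plants no effects,
  no signal boost, and no methylation/panel structure.

One `numpy` Generator drives everything, so a seed reproduces the dataset
bit-identically (tracks are written with 10 significant digits so disk
round trips preserve quantified signal to ~1e-10 relative).

**What passing tests show, and what they do not.**  The generator's
rectangles have no read-sampling noise, no fragment-length effects, no
GC/mappability bias, no peak-calling uncertainty and no correlated noise
between marks; its planted classes are balanced and its signal model
matches the quantifier's assumptions by construction.  Recovery rates on
these data are therefore upper bounds on real-data behavior, useful for
verifying the machinery (labels, rankings, tests, cutoffs), not for
estimating real-world error rates.  In particular, at the default mark
noise (σ = 1.0) the planted presence/absence separation is 5σ per mark,
so classifier posteriors are nearly always certain and essentially all
transcripts are placed unambiguously — real promoter chromatin is far
more ambiguous than this model.

## Problem sizes in the test and acceptance runs

Unit tests use a 2 × 4.5 Mb, 300-transcript, 600-peak study; acceptance
checks use the default study (above), 20-seed repeats for classification
stability, 100-seed repeats for stitching/elbow oracles, 200 repeats for
enrichment and exclusivity recovery, and 5,000-feature simulations for
differential-calling calibration — sizes chosen so the full suite
completes in a few minutes on one CPU while keeping binomial noise on the
checked proportions small.

## Known limitations

* No BAM/bigWig binary parsing; coverage must be interval+value text.
* The common-dispersion NB test is anti-conservative if per-feature
  dispersions vary wildly; with two replicates per state this is the
  identifiable compromise.
* Hierarchical seeding + mixture binarization assume roughly bimodal
  marks; continuous gradients (e.g. bivalent domains) will fall back to
  median splits and depend on the curation purity filter to stay out of
  training.
* The enrichment universe choice materially affects odds ratios; the
  default (merge of query and database) is documented, not canonical.
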