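# epirewire

Analysis of **epigenome rewiring between two cell states** — an
oncogene-high state and an oncogene-low state (e.g. a fusion
transcription factor such as EWS-FLI1 before and after knockdown) — for
computational biologists working with ChIP-seq histone marks, open
chromatin, DNA methylation and RNA-seq from the same perturbation.

The package implements, as a tested reusable library:

* **Genomic interval engine** — BED I/O, overlap counting, nearest-TSS
  distances, strand-aware promoter windows (0-based half-open throughout).
* **Signal quantification** — bedGraph-style coverage integrated over
  regions, normalized to signal-per-million per kb with `log2(x+1)`;
  TSS composite (metagene) profiles; CpG methylation summaries.
* **Differential calling** — one engine for transcript counts and per-peak
  histone signal: median-of-ratios size factors *s_j*, pooled
  method-of-moments NB dispersion α (two replicates per state cannot
  support per-feature dispersion), and a negative-binomial **score test**
  of the state effect.  Under the null the common rate λ solves
  Σ_j (y_j − s_jλ)/(1 + αs_jλ) = 0, and the score statistic
  U²/I is χ²(1) with U = Σ_j x_j (y_j − μ_j)/(1 + αμ_j).
  Features are labeled *correlated* (higher in the oncogene-high state;
  FDR < 0.05, log2FC > 1), *anticorrelated*, or *unchanged*.
* **Semi-supervised chromatin clustering** — regulated transcripts are
  clustered on five promoter marks (H3K4me3, H3K4me1, H3K27ac, H3K56ac,
  H3K27me3), measured in the state where they are more lowly expressed,
  into four prototype classes (C1 fully active; C2 K4-methylated,
  unacetylated; C3 K4me1-only; C4 H3K27me3-repressed).  Ward seeding →
  prototype-pattern curation (presence calls from per-mark Gaussian
  mixtures) → L2-regularized multinomial logistic classification, with an
  unambiguity rule (top posterior ≥ 0.5 and margin ≥ 0.1).
* **Overlap enrichment** — location overlap analysis: per database set a
  2×2 Fisher's exact test over universe units, Haldane–Anscombe-corrected
  odds ratios, BH FDR, rank by p then OR; gene-set enrichment under three
  background schemes (all tested genes / other clusters / opposite
  direction within a cluster).
* **Super-enhancers** — ROSE-style: stitch peaks within 12.5 kb, rank by
  total high-state H3K27ac signal, cut the rank–signal curve at the
  tangent-slope-1 point (both axes scaled to [0,1]); nearest-gene
  annotation and knockdown-dynamics classes.
* **Cell-type specificity** — per-peak share of a K-cell-type
  open-chromatin panel, matched-cell-type exclusivity Fisher test, Q-Q
  quantile comparisons.
* **Synthetic-data generator** — a fully self-contained study with a
  persisted truth ledger, so every stage is testable against planted truth
  without downloads.

## Worked example

`examples/03_chromatin_clustering.py` generates a desk-scale synthetic
study (300 transcripts, 2 × 4.5 Mb genome) and runs differential
expression plus chromatin clustering:

```
correlated: n=90, unambiguous=100.0%, planted-class recovery=100.0%
planted    1   2   3   4
assigned
1         18   0   0   0
2          0  25   0   0
3          0   0  22   0
4          0   0   0  25
```

Each row is an assigned promoter class, each column a planted class: the
diagonal table means every correlated transcript was returned to its
planted chromatin prototype, and all posteriors passed the unambiguity
rule.  The other examples cover simulation (`01`), differential calling
(`02`), region enrichment (`04`), super-enhancers (`05`), cell-type
specificity (`06`) and the full pipeline (`07`); each prints the numbers
it computes with a note on what they mean.  For instance `05` reports

```
stitched enhancers: 238, super: 11, typical: 227
median length  super: 28,481 bp, typical: 1,302 bp
```

— super-enhancers are agglomerates of co-located peaks, hence ~20× longer
than typical enhancers.

## Command line

A thin CLI wraps the library for shell use:

```bash
epirewire simulate --seed 1 --outdir study/
epirewire run --indir study/ --outdir results/ --seed 1
```

Subcommands `cluster`, `enrich`, `superenhancer`, `specificity`, `report`
rerun the pipeline and point at the corresponding outputs.  All parameters
can be overridden with a YAML config (`--config`); unknown keys are
rejected, and every output table carries the configuration digest so
identical configurations rerun to byte-identical files.

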