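# tadlink

Integrative analysis of DNA methylation and gene expression within
topologically associating domains (TADs), built for studies of acute myeloid
leukemia (AML) with mutations in the DNA-methylation machinery
(*DNMT3A*, *IDH1/2*, double mutants) — and for anyone who needs a tested,
reusable implementation of the same statistical machinery on their own
interval/matrix data.

## What it does

Correlation between the methylation of a single CpG and the expression of
its nearest gene is typically weak; regulation acts over 3D-contact
neighbourhoods. `tadlink` therefore tests every gene against every measured
mCpG **within the same TAD**:

* **TAD partition** — called Hi-C domains are merged (overlapping and
  book-ended domains become one TAD) and the uncovered remainder of each
  chromosome is added back, producing a disjoint exhaustive cover.
* **Discovery** — after the study filters (site coverage ≥ 10 in every
  sample, or probe value > 0.3 in > 3 % of samples; top 50 % of
  protein-coding genes by expression), Spearman's ρ and its p-value are
  computed for each within-TAD gene–mCpG pair, BH-corrected genome-wide; a
  pair is significant when |ρ| > 0.5 and FDR < 5 %. Pairs are binned by
  gene–site distance: proximal (≤ 2 kb or inside the gene body),
  intermediate (≤ 500 kb), long-range (> 500 kb).
* **Architecture** — per-gene exon/intron GC, median phyloP-style
  conservation, and MIR/Alu/L1 densities; ECDF-shift curves with one-sample
  Kolmogorov–Smirnov tests against the background gene population;
  B-box (GTTCNANNC) scanning of MIR sequences; TAD-boundary distance and
  MIR-dense vs MIR-zero matched comparisons.
* **DNA-binding-protein enrichment** — a Monte-Carlo null that shuffles
  ChIP-seq peaks within the union of tested genes (1,000 iterations,
  |Z| > 10 significant), with a variant restricted to intronic MIR elements.
* **PPI bridging** — hypergeometric enrichment of physically interacting
  protein pairs where one partner binds the mCpG and the other the
  correlated gene (or a MIR in its introns).
* **SAM** — the Tusher permutation d-statistic with the s0
  coefficient-of-variation criterion and delta/FDR calibration, used for
  differential methylation of retrotransposons, differential expression
  (including the two-replicate pseudo-replicate rule), and distance-SAM.
* **Projection** — rank-normalised expression profiles, PCA fit on normal
  differentiation references only, projection of disease samples, Manhattan
  distance profiles (median-centred per query), distance-SAM and per-cell-type
  hypergeometric enrichment.
* **Synthetic data** — a first-class generator producing genomes, cohorts and
  a 211-sample / 15-cell-type differentiation series with planted, recorded
  ground truth, used by the test suite to verify FDR control and recovery.

## Worked example

Simulate a small dataset and run the discovery stage from the shell:

```
$ tadlink simulate --outdir demo --seed 1 --n-genes 80 --n-sites 600
{'n_tads': 29, 'n_genes': 80, 'n_planted_pairs': 339}

$ tadlink correlate --indir demo --out demo/correlations.tsv
1147 significant of 11064 tested

$ tadlink architecture --indir demo --out demo/architecture.tsv
80 genes profiled
```

The simulated genome has 29 TADs (two 10-Mb chromosomes, mean domain size
1.4 Mb) and 339 planted gene–mCpG couplings. The discovery stage tests the
11,064 within-TAD pairs that survive filtering and reports 1,147 pairs at
|ρ| > 0.5 and FDR < 5 % — the planted couplings (each planted gene correlates
with every driver site of its TAD) plus a small false-positive remainder
controlled by the FDR. `demo/correlations.tsv` lists each pair with its ρ,
p, q, distance and distance bin; `demo/architecture.tsv` holds the per-gene
GC/conservation/repeat-density table used by the ECDF-shift tests.

The same operations are available as library functions
(`tadlink.correlation.correlate_within_tads`, `tadlink.mc.mc_enrichment_z`,
`tadlink.samstat.sam_two_class`, ...), and `tadlink run` executes the whole
pipeline (simulate → correlate → architecture → enrich-dbp → bridge → dmc →
de → project) writing per-stage TSVs plus a manifest with the seeds and
thresholds used.

## Layout

```
src/tadlink/
  core.py         interval algebra, TAD partition, distances, tracks
  tables.py       methylation / expression containers
  io.py           BED, BED12/GTF, bedGraph, TSV, FASTA readers/writers
  simulate.py     synthetic genomes, cohorts, differentiation series
  correlation.py  filtering + within-TAD discovery + downstream summaries
  architecture.py gene/site architecture metrics and tests
  mc.py           Monte-Carlo interval-shuffling enrichment
  bridge.py       PPI bridging enrichment
  stats.py        BH FDR, hypergeometric, chi-squared, Spearman p-values
  samstat.py      SAM and the DMC / DE analyses
  projection.py   rank normalisation, PCA projection, distance-SAM
  pipeline.py     stage orchestration, manifest, caching
  cli.py          `tadlink` command-line interface
```

See `docs/methods.md` for the statistical details, generator assumptions and
known limitations.
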