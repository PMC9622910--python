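# Methods

This note documents the statistical procedures implemented in `tadlink`,
the assumptions of the synthetic-data generator, and the numerical choices
made where the design was genuinely open. It states no empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Coordinates and the TAD partition

All coordinates are 0-based half-open internally. BED input is consumed
unchanged; GTF (1-based inclusive) is converted on read. Called Hi-C
domains are merged — overlapping **and book-ended** domains become a single
TAD — and the complement of the merged set against each declared chromosome
is appended, so the partition is a disjoint, exhaustive cover
(`origin ∈ {called-domain, complement}` is retained per TAD). A feature
belongs to every TAD it overlaps by ≥ 1 bp; a gene spanning k TADs is
eligible for correlation in all k, but a gene–site pair reachable through
more than one TAD is tested once (the hypothesis concerns the pair, not the
(pair, TAD) tuple).

Gene–site distance is measured to the gene-body edges (the body being the
contiguous span of the union of exons and introns): 0 inside the body,
`start − pos` upstream and `pos − end` downstream. The downstream form uses
the half-open end coordinate, i.e. the size of the gap between the site and
the body, matching interval (not per-base) arithmetic. Distance bins:
proximal ≤ 2,000 bp (or within the body), intermediate ≤ 500,000 bp,
long-range beyond. Both cutoffs are closed on the left bin, exactly.

## Discovery stage

Filters (site-level): drop any cytosine with coverage < 10 in **any**
sample; (probe-level): keep probes with a value > 0.3 in more than 3 % of
samples; expression: keep the top 50 % of protein-coding genes by mean
expression. Spearman's ρ is computed as Pearson correlation of average
ranks (vectorised per TAD as a rank-z-score matrix product, verified against
`scipy.stats.spearmanr` in the tests). p-values use the exact permutation
null for untied vectors at n ≤ 9 samples (cached enumeration of all n!
rankings) and the t approximation otherwise. Benjamini–Hochberg correction
is applied **genome-wide across all tested pairs** — the correction scope
was an open choice; per-TAD correction was rejected as anticonservative for
small TADs. A pair is significant iff |ρ| > 0.5 and q < 0.05. Zero-variance
vectors are skipped and counted (`table.attrs['n_skipped_zero_variance']`).

Downstream summaries: CpG-island methylation is the unweighted mean of
member sites; the W set ranks genes by max |ρ| over their sites in a bin and
keeps the n = 1,000 weakest (lexicographic tie-break); shared-site gene
pairs use an upper-tail hypergeometric over the sites tested for both genes;
cohort comparison recomputes ρ per pair on the alternate sample set and
applies a paired one-sided Wilcoxon signed-rank on |ρ| (the comparison test
was unspecified in the design; Wilcoxon was chosen for its freedom from
normality assumptions on bounded coefficients). The enrichment of
positive/negative significant correlations in the proximal bin is a
one-sided chi-squared against the tested-pair bin proportions (p halved when
the proximal cell is enriched, with an exact Monte-Carlo fallback whenever
an expected count drops below 5).

## Architecture metrics and tests

Per gene: exonic/intronic length from merged exons; GC and conservation as
coverage-weighted means / per-base weighted medians over track steps (bases
without track values are excluded; genes with < 50 % track coverage are
flagged); repeat-family density = overlapped bases / region length.
Intronless genes carry undefined intronic fields and drop out of
intron-based tests.

The ECDF-shift curve is `background ECDF − set ECDF` on the union of both
samples' jump points, so positive values mean the set is shifted toward
higher metric values; since both ECDFs are constant between grid points, the
one-sample KS statistic D equals max |curve| by construction, and its
p-value uses the exact one-sample KS distribution (`scipy.stats.kstwo`) with
the background ECDF treated as the reference CDF — slightly conservative for
a discrete reference. Two-sample KS is used only where two finite sets are
genuinely compared: TAD-boundary distances and the MIR-zero matched test.

B-box scanning counts matches of GTTCNANNC on the forward strand plus its
reverse complement (GNNTNGAAC) in the same segment; overlapping matches all
count; any non-ACGT character fails a fixed motif position but satisfies an
N position (permissive N, strict consensus).

The MIR-zero comparison takes the top decile of intronic-MIR density and the
MIR-zero genes, matches them on CpG density (nearest neighbour without
replacement within a caliper, default 0.2 SD of CpG density — no matching
algorithm was prescribed) and compares per-gene max |ρ| by two-sample KS;
fewer than 20 matched pairs is an error, since a decile-based contrast is
meaningless at that size. At the default 200-gene synthetic scale this guard
fires, so the packaged test of this operation uses a 500-gene genome with
uniform CpG placement.

## Monte-Carlo DBP enrichment

Observed = number of features (gene bodies, MIR elements, sites) overlapped
by ≥ 1 ChIP-seq peak. Null: each peak is placed independently and uniformly
over all start positions at which it fits **entirely inside one segment** of
the shuffling space (the merged union of all tested genes, or of the
intronic MIRs of a gene set in MIR mode); longer segments therefore receive
proportionally more mass, lengths are conserved, and shuffled peaks may
overlap one another — forbidding overlap would bias the null for dense peak
sets. Z = (observed − null mean)/null SD over n = 1,000 iterations by
default; a zero null SD is reported as a degenerate flag, never as an
infinite Z; |Z| > 10 is the significance convention. In MIR mode, peaks
longer than the largest MIR are centre-trimmed to fit (they could otherwise
never be placed). The null is evaluated in a linearised copy of the space
(segments laid out as disjoint blocks) so one iteration is a few vector
operations.

## PPI bridging

For an ordered interacting pair (A, B): population = all correlated pairs,
draws = pairs whose mCpG carries an A peak, successes = pairs whose gene
carries a B peak (gene mode: anywhere on the body; MIR mode: on an intronic
MIR footprint), observed = pairs with both; upper-tail hypergeometric, BH
across all tested ordered pairs. (A@site, B@gene) and (B@site, A@gene) are
distinct hypotheses; a protein bound at both ends contributes to both
margins; self-pairs are excluded by default. The hypergeometric framing
matches a background of "all possible pairs among the correlated pairs"; a
permutation alternative would shuffle pair membership, and the
hypergeometric is its analytic analogue under fixed margins.

## SAM

Two-class d-statistic `d_i = (mean2 − mean1) / (s_i + s0)` with the pooled
scatter `s_i = sqrt((1/n1 + 1/n2) (SS1 + SS2)/(n1 + n2 − 2))` (the original
Tusher formula with class-size coefficients, not the equal-variance
simplification). s0 minimises the coefficient of variation of the
d-spread: d is recomputed at each 5-percentile candidate of s, its median
absolute deviation is taken within 100 percentile windows of s, and the
candidate with the smallest CV of those window spreads wins; a strictly
positive floor is applied when zero-scatter features exist. The null uses
label permutations (all distinct assignments when fewer than the requested
5,000 exist); sorted permuted d vectors are averaged into the expected order
statistics. For a threshold delta, the cutpoints are the smallest/largest
observed d whose deviation from expectation reaches ±delta; estimated
FDR = π0 × median permuted call count / observed call count, with π0
estimated from the central 50 % of the permuted d distribution; the chosen
delta is the smallest whose estimated FDR meets the 5 % target.

Differential methylation per retrotransposon family uses sites overlapping
the family with coverage > 10 in every sample and non-zero methylation in
≥ 2 samples of each class (the eligibility read is deliberately one read
stricter than the discovery filter, following the analysis description
verbatim), then reports the %DMC among tested family sites and the
hyper/hypo split by the sign of d. DMC annotation assigns each site one
category with precedence protein-coding > non-coding > intergenic and
compares the DMC split to the tested-site proportions by chi-squared.
Differential expression log2-transforms with offset 1 (configurable); when
a class has exactly two replicates and the pseudo-replicate rule is
requested, their per-gene mean is appended as a third column before the
statistic.

## Projection and distance-SAM

Expression profiles are rank-normalised per sample (highest value = highest
rank, average ranks on ties), making every downstream quantity invariant to
strictly monotone per-sample transforms. PCA is fit on the reference
(normal) samples only; query samples are centred with the **reference**
gene means and projected on the reference eigenvectors; the default number
of retained components is the smallest reaching 80 % variance (display
only — distances are computed in full rank space, not PC space). The
distance profile is the reference × query Manhattan matrix, median-centred
per query column. Distance-SAM treats reference samples as features and the
two query groups as classes; significant references split by direction
(closer to / further from the second group) and are tested per cell type by
one-sided hypergeometric, BH-corrected.

## Synthetic-data generator

The generator defines the study conditions; its defaults are fixed, not
tuned per analysis:

* **Genome** — two 10-Mb chromosomes; domain lengths Gamma-distributed with
  mean 1.4 Mb, separated by 2–10 kb boundary gaps with occasional larger
  unclaimed gaps (these become complement TADs); 200 genes (40 %
  "regulatable", 10 % non-coding), 1–12 exons of 100–300 bp. Regulatable
  genes have MIR-dense (target 0.15), GC-rich (~0.55), weakly conserved
  introns; independent genes are MIR-sparse (0.03), and 40 % of them carry
  no intronic MIR at all — giving the MIR-zero contrast real membership.
  MIR lengths are uniform 130–260 bp, Alu ≈ 300 bp, L1 0.5–6 kb; divergence
  scores are Gaussian per family (MIR 32 ± 6, Alu 14 ± 6, L1 22 ± 8 %).
  Tracks are 200-bp step functions with 2 % coverage gaps. 30 % of MIRs
  carry an intact B-box (random orientation); sequence exists only under
  repeat footprints, with chance B-box cores scrubbed outside the planted
  ones so the planted fraction is interpretable.
* **Cohort** — 16/9/11 DNMT3A/IDH/double samples by default (36 total).
  Methylation group distributions (invented; only the direction was given):
  DNMT3A-low Beta(2,8), IDH-high Beta(8,2), double intermediate Beta(5,5),
  wild type Beta(2.5,2.5) (same mean, doubled dispersion). Planting uses a
  per-TAD latent factor: a TAD's driver sites share the latent methylation
  signal (site noise SD 0.05) and each planted gene reads it through
  log2-expression = α + β·m + ε with β = 3 and ε SD = 0.6, which yields
  |ρ| ≈ 0.8 against driver sites under the default group mixture. A gene
  cannot be independently correlated at 0.8 with many mutually independent
  sites, so the latent-factor construction is what makes a 10 % planted-pair
  fraction realisable with 200 genes — and mirrors the observation that a
  small subset of mCpGs explains many genes per TAD. 98.5 % of planted
  couplings are negative. planted-pair fraction = planted-gene fraction
  (1/3) × driver-site fraction; an infeasible combination is a design error.
  Wild-type samples, when present, are decoupled from the planted term
  (`wt_null`), supporting the cross-cohort coefficient comparison.
  Coverage is 10 + Poisson(30) with 2 % dropout sites given a sub-threshold
  sample.
* **Planted regulatory architecture** — driver sites preferentially sit on
  MIRs (25 %), enhancers (25 %) and MIR-enhancers (10 %); 40 % of enhancers
  are placed directly over intronic MIRs of regulatable genes. Bridging is
  planted as heterogeneity across TADs: in 70 % of eligible TADs the drivers
  are MIR-enhancer sites and the planted genes their host genes; the
  site-binding proteins (THRA, BCOR) cover 85 % of MIR-enhancer sites and
  the MIR-binding partners (MEF2A, PTBP1) cover 90 % of the enhancer-MIRs,
  with deliberately modest background binding — the enrichment signal comes
  from this between-TAD heterogeneity, since a uniformly bridged population
  would show independent margins. Target-gene DBPs (RUNX1, FLI1) put 80 % of
  their peaks on a recorded target set.
* **Differentiation series** — 15 cell types, 211 samples (15 + 14 × 14);
  10 % of genes DE per type vs the root (HSC), effects ±1.5 ± 0.3 log2,
  noise SD 0.4; upregulated genes drawn from the regulatable class at odds
  ratio 4.

What the generator does **not** emulate: read-level sequencing error,
covariate structure (age, sex, batch), genuine nucleotide evolution,
chromatin-state-dependent peak shapes, or correlated methylation outside
the planted TAD factors. Passing tests therefore demonstrate correctness of
the statistical machinery and its operating characteristics under the
planted model, not performance on any particular clinical dataset.

## Problem sizes used by the packaged checks

The test suite and acceptance script run at desk scale: 20 cohorts of 36
samples over a 20-Mb genome for FDR control; 1,000-feature × 10-sample
matrices with 200 permutations (of the 252 possible at 5 + 5) for SAM
operating characteristics; 100 repetitions at 150 iterations for Monte-Carlo
null calibration and 1,000 iterations for the sensitivity check; 20
replicate cohorts for bridge recovery. The SAM default of 5,000 permutations
and the Monte-Carlo default of 1,000 iterations remain the library defaults.

## Known limitations

* The exact Spearman null is enumerated only for n ≤ 9 untied samples; tied
  small-sample vectors fall back to the t approximation.
* KS p-values against a discrete background ECDF are conservative.
* The Monte-Carlo shuffle is not GC- or chromatin-matched.
* The delta search in SAM follows the classic cutpoint rule; in pathological
  cases where the low and high cutpoints cross, the lower side is dropped
  rather than reporting an inverted interval.
* Stage caching in the pipeline is manifest-hash based and conservative: any
  configuration change reruns everything.
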