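# Methods

This note documents the models, parameter choices and numerical rules the
package implements, and what the synthetic-data tests do and do not show
about real data.

## Reproducible-site merging

Replicate peak calls carry single-bp summits. The published definition of
reproducibility — the same location in ≥ 2 replicates, summit distance
< 100 bp, site = 201-bp window on the rounded mean summit — does not fix a
clustering algorithm, so the package uses a deterministic seed-and-absorb
rule: peaks are ordered by descending caller score (ties broken by
chromosome, coordinate, then replicate id); the highest unassigned peak
seeds a cluster and absorbs, from each other replicate, the nearest
unassigned summit strictly within 100 bp of the seed (at most one member
per replicate, nearest ties to the lower coordinate); clusters with fewer
than `min_support` (default 2) distinct replicates are discarded with
their peaks consumed. The rule is order-invariant, oracle-checkable by
brute force, and uses scores only for seeding priority. The mean summit
rounds halves toward the lower coordinate so results are platform-stable.
Windows truncated at chromosome ends are retained and flagged.

## Motif scanning, coincidence and enrichment

Scanning is exact consensus matching of the G-box (CACGTG) and PBE-box
(CACATG) on both strands; the palindromic G-box is reported once per
position on '+', a PBE match appearing in the forward text as CATGTG is
reported on '−', and positions containing N never match. The two
consensus classes are disjoint, so no occurrence is double-counted. A
motif's position for distance purposes is its third base (start + 2), a
fixed integer proxy for the centre of an even-length word. Coincidence is
a strict < 100 bp summit-to-nearest-centre test.

Enrichment compares the fraction of site windows (201/101/51 bp, centred
on summits) containing ≥ 1 occurrence with the mean fraction over 100
simulations, each drawing as many uniform-random genomic windows of the
same width as there are sites (chromosomes weighted by valid start count;
windows lie fully inside chromosomes and may overlap each other or real
sites, since the published procedure states no exclusion). A zero null
mean flags the fold undefined rather than returning infinity.

## Promoter assignment

A site is intergenic when its mean summit (a point, not the 201-bp
window) lies in no annotated gene span. For assignment, each strand is
considered separately: the nearest gene whose TSS is downstream of the
summit in the gene's own 5'→3' sense, at distance 0 < d ≤ 5000 bp, is a
candidate; it is assigned unless any other gene's span or TSS (either
strand) intersects the open summit–TSS interval. "Intervening" thus
blocks on both span and TSS — the published analysis curated this
manually, and the explicit rule is the conservative reading. A summit
exactly at a TSS is not 5'-flanking and is not assigned. One site can
yield two assignments (divergent promoters). Distances are binned at
≤ 3 kb vs 3–5 kb (upper bounds inclusive).

## Differential expression

The SSTF contract (≥ 2-fold and adjusted P ≤ 0.05, both boundaries
inclusive) is served by a self-contained NB pipeline rather than an
external DE package, so the stage is an explicit computation:

* **Size factors** — median-of-ratios against the per-gene geometric mean
  over genes positive in all samples, rescaled to geometric mean 1; if no
  gene qualifies, total-count factors are used with a warning.
* **Common dispersion** — method of moments on normalized counts,
  φ = max(0, (s² − m̄)/m̄²) per gene × genotype with ≥ 2 replicates, pooled
  as the median over entries with m̄ > 5 (the floor avoids the heavy
  small-mean bias of the moment estimator).
* **Exact test** — per gene, normalized counts are summed per group and
  rounded. A sum of n i.i.d. NB(μ, φ) variables is NB(nμ, φ/n), and
  conditional on the total the split follows a negative hypergeometric
  law with shape parameters n_A/φ and n_B/φ that is free of μ, so no mean
  needs to be estimated under the null. The two-sided p-value sums the
  probabilities of all splits no more likely than the observed one (with
  a 1e-10 relative tolerance on the pmf comparison); φ = 0 reduces to a
  Binomial(t, n_A/(n_A+n_B)) conditional test. All-zero genes get p = 1
  and log2FC = 0 and are excluded from the BH denominator.
* **Fold change** — ratio of normalized group means with a 0.5
  pseudo-count on each side to avoid infinities.
* **Multiple testing** — Benjamini–Hochberg step-up per contrast, clipped
  at 1. The adjusted-P procedure is configurable in principle but BH is
  the default and the one the tests pin.

Results are not expected to be numerically identical to edgeR-style
tagwise-shrinkage analyses; the contract is the SSTF definition, null
calibration (super-uniform p-values at the true φ, adjusted-P ≤ 0.05
fraction ≤ 0.05 under a global null) and power on planted folds.

Composite sets are pure set algebra over SSTF flags: quartet-regulated =
SSTF(*pifq*/WT); PIF3-regulated = SSTF(*pif3*/WT) ∪ SSTF(*pifq*/*pif145*);
trio-regulated = SSTF(*pif145*/WT) ∪ SSTF(*pifq*/*pif3*). With the mutant
genotype first in every contrast, a negative log2FC means the missing
PIF(s) normally induce the gene; a gene whose SSTF-passing defining
contrasts disagree in sign is reported as direction-ambiguous rather than
forced into either split.

## Classification and contribution partitioning

W/X/Y/Z are a truth table over (bound, PIF3-regulated, quartet-regulated)
and partition the bound genes by construction; regulated-but-unbound genes
are tabulated separately. YZ1.5 promotion requires a strict > 1.5
*pif145*/*pifq* normalized fold in the PIF-induced direction plus an
unadjusted one-sided two-sample t-test (P < 0.05) on log2 normalized
replicate values. The confirmation is one-sided because the criterion it
mirrors is a statistically significant PIF3-*promoted* increase — a
directional claim; the directional test also has adequate power (≥ 80% at
a planted 1.8-fold, baseline 500, φ = 0.05, 3 replicates) where a
two-sided version would not.

Contributions apply the published percentage formula to normalized
RNA-seq genotype means (the original assay was RT-qPCR; the statistic,
not the assay, is the contract). Contributions may be negative or exceed
100 and are not clipped. The denominator E(WT) − E(*pifq*) is flagged
(and percentages set to NaN) when |E(WT) − E(*pifq*)| < 10⁻⁶·E(WT) or
both means are below 1 normalized count. The PIF3/trio share
decomposition sums to exactly 100 wherever defined, an algebraic identity
the tests assert. Missing triple-mutant genotypes drop the corresponding
column rather than reporting zero.

## Synthetic data

The generator emulates the inputs end to end with recorded ground truth:

* **Genome and annotation** — uniform-random A/C/G/T (configurable GC)
  over 5 chromosomes × 250 kb by default, carrying 150 non-overlapping
  stranded genes (500–1500 bp) separated by ≥ 6 kb so each has a clear
  5-kb promoter. The 5-chromosome layout mirrors the organism the method
  targets; keeping planted targets to ~17% of genes preserves the
  median-of-ratios assumption that most genes are non-differential.
* **True sites** — 25 by default, each 200–4800 bp upstream of its target
  TSS in the adjacent intergenic gap (so no gene intervenes by
  construction), with a G- or PBE-box written within 50 bp of the summit;
  the 50-bp bound keeps motif coincidence robust to replicate jitter
  while still exercising nonzero summit–motif distances. Background motif
  occurrences arise naturally at the base-composition rate.
* **Peak calls** — per replicate, each true site survives with
  probability 0.9, its summit displaced by rounded N(0, 10 bp); 20 decoy
  peaks per replicate are placed uniformly, ≥ 500 bp from every true
  summit so merging specificity is well defined. True peaks draw higher
  caller scores (U(50,100)) than decoys (U(10,60)), as real peak callers
  score reproducible sites more strongly.
* **Counts** — additive activation on the mean scale: gene g in a
  genotype retaining PIF subset S has mean size_factor × (baseline +
  Σ_{i∈S} a_i(g)), NB-distributed with φ = 0.05 (Poisson at φ = 0), three
  replicates per genotype, baseline 100. Planted targets draw
  a₃ ~ U(1.5, 3)·baseline — so the PIF3 gain-of-function contrast clears
  the two-fold bar by design — and a₁, a₄, a₅ ~ U(0, 2)·baseline. The
  additive truth makes the contribution statistic exactly recoverable:
  on noise-free means, percent_i = 100·a_i/Σa identically.
* **Reproducibility** — each artifact (genome, peaks, counts) has its own
  RNG stream derived from the master seed, so outputs are bit-identical
  under a fixed seed and stages can be regenerated independently.

What the generator does *not* model: read-level data (FASTQ/alignment),
fragment-size and mappability biases, 3'-end library artifacts,
correlated gene expression, isoform structure, or peak-caller behaviour.
Passing tests therefore demonstrate the correctness of the computations
and their calibration under the stated noise model, not performance on
real sequencing data, whose genome-scale peak and gene-set counts depend
on the deposited experimental inputs.

## Problem sizes and tolerances

Default test and acceptance runs use the generator defaults above
(1.25 Mb genome, 150 genes, 25 sites, 100-fold enrichment simulations
reduced to 20–50 in end-to-end runs), exact-test totals up to a few
thousand, and 3 generator seeds for seed-averaged recovery statistics —
sizes chosen so every oracle can be brute-forced and the whole suite runs
in well under a minute. Recovery bars are ≥ 90% Class-Z recall and ≤ 10
percentage points mean contribution error (at baseline 1000 for the
noisy-recovery check, matching its derivation); identities (share sum,
class partition) are exact to floating point.

## Known limitations

* Common (not tagwise) dispersion; genes with gene-specific
  overdispersion are tested at the pooled φ.
* Consensus-only motif model; no PWM scoring or degenerate E-box classes.
* Single gene model per locus; no isoform-resolved TSS handling.
* The exact test rounds normalized group sums to integers, a negligible
  approximation at the count depths simulated here but untested at very
  low counts with strongly unequal library sizes.
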