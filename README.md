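# quartet-hub

Integrated ChIP-seq × RNA-seq identification of the direct targets of a
transcription factor, and partitioning of shared transcriptional control
among closely related factors.

The package re-creates, as a tested and reusable pipeline, the analysis used
to define direct targets of the Arabidopsis bHLH factor **PIF3** and to
dissect how the four Phytochrome-Interacting Factors of the PIF quartet
(PIF1, PIF3, PIF4, PIF5) share regulation of common target genes in
dark-grown seedlings. It is aimed at regulatory genomicists who want each
stage of such an integration — replicate peak merging, consensus-motif
analysis, promoter assignment, exact-test differential expression, class
algebra and contribution partitioning — as an explicit, oracle-tested
computation rather than a black box, together with a synthetic-data
generator that plants a known truth under every stage.

## The method

**Reproducible binding sites.** Replicate-specific ChIP peak summits are
clustered across ≥ 2 biological replicates: summits within 100 bp of a
seed summit (highest caller score first) form one site, represented by the
201-bp window centred on the rounded mean summit.

**Motifs.** Sites are scanned for the G-box (CACGTG) and the PBE-box
(CACATG) consensus on both strands; a site is *motif-coincident* when the
nearest motif centre is strictly within 100 bp of the mean summit. Motif
enrichment is measured against random genomic windows of the same width
(default 100 simulations; fold = observed / null mean).

**Promoter assignment.** An intergenic, motif-coincident site is assigned
to the nearest gene on each strand whose TSS lies downstream of the summit
in the gene's sense orientation, within 5 kb, with no intervening gene —
so one site can serve a divergent gene pair.

**SSTF calling.** For genotypes WT, *pif3*, *pif145*, *pifq* (and the
other *pif*-triple mutants), Statistically-Significant Two-Fold genes in a
contrast satisfy |fold change| ≥ 2 with Benjamini–Hochberg adjusted
P ≤ 0.05, from a self-contained negative-binomial exact test
(median-of-ratios size factors, method-of-moments common dispersion φ,
conditional test on the group totals — a negative hypergeometric law with
shapes n<sub>g</sub>/φ, reducing to a binomial split at φ = 0).

**Composite sets and classes.** PIF3-regulated = SSTF(*pif3*/WT) ∪
SSTF(*pifq*/*pif145*); quartet-regulated = SSTF(*pifq*/WT); trio-regulated
= SSTF(*pif145*/WT) ∪ SSTF(*pifq*/*pif3*). Bound genes are partitioned:
**W** bound only, **X** bound + PIF3-regulated, **Y** bound +
quartet-regulated, **Z** bound + both; Y-class genes with a moderate
(> 1.5-fold) but statistically supported *pif145*/*pifq* increase are
promoted to **YZ1.5**.

**Contribution partitioning.** With E(g) the mean normalized expression in
genotype g, the autonomous contribution of PIF *i* (triple mutant m*ᵢ*
retaining only PIF *i*) is

    percent_i = 100 · (E(m_i) − E(pifq)) / (E(WT) − E(pifq))

and the PIF3 vs PIF1/4/5-trio shares,
100·(E(*pif145*) − E(*pifq*)) / (E(WT) − E(*pifq*)) and
100·(E(WT) − E(*pif145*)) / (E(WT) − E(*pifq*)), sum to exactly 100.

The printed direct-target gene table (36 rows: 19 Class Z, 17 Class YZ1.5,
with rapid-light-repression and reciprocal light/shade annotations) ships
as a queryable fixture.

## Worked example

Generate a synthetic dataset (five 250-kb chromosomes, 150 genes, 25
planted binding sites with known per-PIF activation weights; four ChIP
replicates; NB counts for seven genotypes × 3 replicates) and run the full
pipeline:

```bash
quartet-hub simulate --out demo --seed 42
cat > demo/run.yaml <<EOF
genome_fasta: demo/genome.fa
annotation_gff: demo/genes.gff3
peak_files:
  - demo/peaks_rep1.narrowPeak
  - demo/peaks_rep2.narrowPeak
  - demo/peaks_rep3.narrowPeak
  - demo/peaks_rep4.narrowPeak
counts_tsv: demo/counts.tsv
sample_map_tsv: demo/samples.tsv
out_dir: demo/out
EOF
quartet-hub run --config demo/run.yaml --seed 42
```

which prints

```
{"class_counts": {"none": 120, "W": 5, "Z": 22, "Y": 3}, "n_sites": 26}
```

26 reproducible sites were merged from the four replicates; of the 30
bound genes, 22 are Class Z (bound and in both the PIF3- and
quartet-regulated sets) and the 3 Y-class genes are all promoted to YZ1.5
by the moderate-fold rule — together recovering all 25 planted direct
targets. `demo/out/report.json` also records the motif enrichment folds,
which rise toward the summit exactly as expected for planted motifs
(G-box: 11.0 at 201 bp, 15.4 at 101 bp, 25.9 at 51 bp), and the TSS
distance split (63% of assignments within 3 kb). Per-stage artifacts
(sites, DE tables, classification, contribution matrix) are written
alongside it.

Query the packaged direct-target table:

```bash
$ quartet-hub table1-counts --where "category=Class Z"
19
```

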