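"""Synthetic genomes, peak calls and count matrices with recorded truth.

The generator emulates the data the pipeline consumes: random chromosome
sequences carrying non-overlapping stranded genes; true binding sites
planted in 5'-flanking DNA within 5 kb of a target TSS, each with a G- or
PBE-box written within 100 bp of the site centre; replicate peak calls with
Gaussian summit jitter, per-replicate dropout and uniform decoy peaks; and
negative-binomial counts for the seven *pif*-mutant genotypes under an
additive activation model, mean = size_factor * (baseline + sum of the
activation weights of the PIFs retained by the genotype).  The additive
truth makes the per-PIF contribution statistic exactly recoverable on
noise-free means: the planted contribution of PIF i is 100 * a_i / sum(a).

Ground truth (site positions, site-to-gene map, planted contributions) is
recorded so recovery can be scored exactly.  Each output artifact (genome,
peaks, counts) draws from its own RNG stream derived from the master seed,
so stages can be regenerated independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from quartet_hub.de import GENOTYPE_PIFS, CountMatrix
from quartet_hub.genes import GeneModel
from quartet_hub.peaks import DEFAULT_MOTIFS, PeakCall, reverse_complement

PIFS = (1, 3, 4, 5)


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic dataset.

    Defaults are desk-scale: five 250-kb chromosomes carrying 150 genes
    and 25 true binding sites (so most genes are non-differential, as
    median-of-ratios normalization assumes), four ChIP replicates with
    10-bp summit jitter and 10% dropout, and NB counts (dispersion 0.05)
    for three biological replicates per genotype, mirroring the
    four-replicate ChIP / three-replicate RNA design the pipeline targets.
    """

    genome_length: int = 250_000
    n_chromosomes: int = 5
    n_genes: int = 150
    gene_length_range: tuple[int, int] = (500, 1500)
    n_true_sites: int = 25
    motif_repertoire: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_MOTIFS))
    summit_jitter_sd: float = 10.0
    replicate_dropout_prob: float = 0.1
    n_decoy_peaks: int = 20
    n_replicates: int = 4
    baseline_mean: float = 100.0
    #: explicit per-gene activation weights {gene_id: {pif: a_i}}; when None,
    #: weights are drawn for the true-target genes (see simulate_genome).
    activation_weights: dict[str, dict[int, float]] | None = None
    dispersion: float = 0.05
    library_sizes: dict[str, float] | None = None
    n_bio_reps: int = 3
    gc_content: float = 0.5
    #: minimum intergenic gap, sized to hold a 5-kb promoter search space
    min_gap: int = 6000
    seed: int = 0

    def validate(self) -> None:
        if self.genome_length <= 0 or self.n_chromosomes <= 0:
            raise ValueError("genome_length and n_chromosomes must be positive")
        if not 0 <= self.replicate_dropout_prob <= 1:
            raise ValueError("replicate_dropout_prob must be in [0, 1]")
        if not 0 < self.gc_content < 1:
            raise ValueError("gc_content must be in (0, 1)")
        if self.summit_jitter_sd < 0:
            raise ValueError("summit_jitter_sd must be nonnegative")
        if self.dispersion < 0:
            raise ValueError("dispersion must be nonnegative")
        if self.baseline_mean < 0 or self.n_decoy_peaks < 0 or self.n_true_sites < 0:
            raise ValueError("counts must be nonnegative")
        if self.n_replicates < 1 or self.n_bio_reps < 1:
            raise ValueError("replicate counts must be >= 1")
        if self.gene_length_range[0] > self.gene_length_range[1] or self.gene_length_range[0] < 1:
            raise ValueError("bad gene_length_range")
        if self.activation_weights is not None:
            for g, w in self.activation_weights.items():
                if any(a < 0 for a in w.values()):
                    raise ValueError(f"negative activation weight for {g}")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, stream])


@dataclass
class TrueSite:
    chromosome: str
    summit: int
    gene_id: str
    motif_id: str


@dataclass
class GroundTruth:
    sites: list[TrueSite]
    #: site index -> target gene id(s)
    true_target_map: dict[int, list[str]]
    #: gene -> {pif: raw additive weight a_i}
    activation_weights: dict[str, dict[int, float]]
    #: gene -> {pif: 100 * a_i / sum(a)} for genes with sum(a) > 0
    planted_contributions: dict[str, dict[int, float]]


def _random_sequence(rng: np.random.Generator, length: int, gc: float) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=length, p=probs)])


def _draw_weights(rng: np.random.Generator, baseline: float) -> dict[int, float]:
    """Weights for one target gene: a robust autonomous PIF3 effect (1.5-3x
    the baseline, so the gain-of-function contrast clears two-fold) and
    moderate 0-2x effects for PIF1/4/5."""
    w = {i: float(rng.uniform(0.0, 2.0 * baseline)) for i in (1, 4, 5)}
    w[3] = float(rng.uniform(1.5 * baseline, 3.0 * baseline))
    return w


def simulate_genome(
    config: SimulationConfig,
) -> tuple[dict[str, str], list[GeneModel], GroundTruth]:
    """Generate chromosome sequences, a gene annotation and ground truth.

    Genes are packed without overlap, separated by at least ``min_gap`` bp
    so every gene has room for a 5-kb promoter.  True sites are placed in
    the gap on the 5' side of their target gene, 200-4800 bp upstream of
    the TSS, with a motif from the repertoire written within 50 bp of the
    summit (on a random strand) so summit-motif coincidence survives
    replicate jitter.  Raises on infeasible packing.
    """
    config.validate()
    rng = config.rng(0)
    if config.n_true_sites > config.n_genes:
        raise ValueError("n_true_sites cannot exceed n_genes")

    chrom_names = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    genome = {c: _random_sequence(rng, config.genome_length, config.gc_content) for c in chrom_names}

    # round-robin gene counts per chromosome
    per_chrom = [config.n_genes // config.n_chromosomes] * config.n_chromosomes
    for i in range(config.n_genes % config.n_chromosomes):
        per_chrom[i] += 1

    annotation: list[GeneModel] = []
    gene_no = 0
    for c, n in zip(chrom_names, per_chrom):
        if n == 0:
            continue
        lengths = rng.integers(config.gene_length_range[0], config.gene_length_range[1] + 1, size=n)
        slack = config.genome_length - int(lengths.sum()) - config.min_gap * (n + 1)
        if slack < 0:
            raise ValueError(
                f"infeasible packing on {c}: {n} genes of total length "
                f"{int(lengths.sum())} bp plus {config.min_gap}-bp gaps exceed "
                f"{config.genome_length} bp"
            )
        extra = rng.multinomial(slack, np.full(n + 1, 1.0 / (n + 1)))
        pos = 0
        for k in range(n):
            pos += config.min_gap + int(extra[k])
            start = pos + 1  # 1-based
            end = start + int(lengths[k]) - 1
            gene_no += 1
            strand = "+" if rng.random() < 0.5 else "-"
            annotation.append(GeneModel(f"gene_{gene_no:04d}", c, strand, start, end))
            pos = end

    # plant true sites upstream of a random subset of genes
    target_idx = rng.choice(len(annotation), size=config.n_true_sites, replace=False)
    motif_ids = sorted(config.motif_repertoire)
    sites: list[TrueSite] = []
    target_map: dict[int, list[str]] = {}
    mutable = {c: list(genome[c]) for c in genome}
    for si, gi in enumerate(sorted(int(i) for i in target_idx)):
        gene = annotation[gi]
        offset_tss = int(rng.integers(200, 4801))
        summit = gene.tss - offset_tss if gene.strand == "+" else gene.tss + offset_tss
        motif_id = motif_ids[int(rng.integers(len(motif_ids)))] if motif_ids else None
        if motif_id is not None:
            center = summit + int(rng.integers(-50, 51))
            consensus = config.motif_repertoire[motif_id]
            if rng.random() < 0.5:
                consensus = reverse_complement(consensus)
            start0 = center - 2 - 1  # 0-based start of the 6-mer
            mutable[gene.chromosome][start0 : start0 + 6] = list(consensus)
        sites.append(TrueSite(gene.chromosome, summit, gene.gene_id, motif_id or ""))
        target_map[si] = [gene.gene_id]
    genome = {c: "".join(mutable[c]) for c in mutable}

    if config.activation_weights is not None:
        weights = {g: dict(w) for g, w in config.activation_weights.items()}
    else:
        weights = {s.gene_id: _draw_weights(rng, config.baseline_mean) for s in sites}
    contributions = {}
    for g, w in weights.items():
        total = sum(w.values())
        if total > 0:
            contributions[g] = {i: 100.0 * w.get(i, 0.0) / total for i in PIFS}
    truth = GroundTruth(sites, target_map, weights, contributions)
    return genome, annotation, truth


def simulate_chip_replicates(
    truth: GroundTruth,
    config: SimulationConfig,
    genome: dict[str, str] | None = None,
) -> list[list[PeakCall]]:
    """Replicate peak calls: each true site appears in a replicate with
    probability 1 - dropout, its summit displaced by rounded N(0, jitter_sd),
    plus uniform decoy peaks kept >= 500 bp from every true summit.  True
    peaks draw higher caller scores than decoys."""
    config.validate()
    rng = config.rng(1)
    chrom_len = (
        {c: len(s) for c, s in genome.items()}
        if genome is not None
        else {c: config.genome_length for c in {s.chromosome for s in truth.sites}}
        or {f"chr{i + 1}": config.genome_length for i in range(config.n_chromosomes)}
    )
    chroms = sorted(chrom_len)
    lens = np.array([chrom_len[c] for c in chroms], dtype=float)
    true_by_chrom: dict[str, list[int]] = {c: [] for c in chroms}
    for s in truth.sites:
        true_by_chrom.setdefault(s.chromosome, []).append(s.summit)

    replicates: list[list[PeakCall]] = []
    for r in range(config.n_replicates):
        rep_id = f"rep{r + 1}"
        peaks: list[PeakCall] = []
        for s in truth.sites:
            if rng.random() < config.replicate_dropout_prob:
                continue
            jitter = int(round(rng.normal(0.0, config.summit_jitter_sd))) if config.summit_jitter_sd > 0 else 0
            summit = int(np.clip(s.summit + jitter, 1, chrom_len[s.chromosome]))
            peaks.append(PeakCall(s.chromosome, summit, float(rng.uniform(50.0, 100.0)), rep_id))
        placed = 0
        while placed < config.n_decoy_peaks:
            ci = int(rng.choice(len(chroms), p=lens / lens.sum()))
            c = chroms[ci]
            pos = int(rng.integers(1, chrom_len[c] + 1))
            if any(abs(pos - t) < 500 for t in true_by_chrom.get(c, [])):
                continue
            peaks.append(PeakCall(c, pos, float(rng.uniform(10.0, 60.0)), rep_id))
            placed += 1
        replicates.append(peaks)
    return replicates


def simulate_counts(
    truth: GroundTruth,
    config: SimulationConfig,
    annotation: list[GeneModel] | None = None,
    genotypes: list[str] | None = None,
) -> CountMatrix:
    """NB counts for the requested genotypes under the additive model.

    The mean for gene g in a genotype retaining PIF subset S is
    size_factor * (baseline + sum_{i in S} a_i(g)); counts are NB with the
    configured dispersion (Poisson at dispersion 0).
    """
    config.validate()
    rng = config.rng(2)
    if genotypes is None:
        genotypes = list(GENOTYPE_PIFS)
    unknown = [g for g in genotypes if g not in GENOTYPE_PIFS]
    if unknown:
        raise ValueError(f"unknown genotype label(s): {unknown}")
    if annotation is not None:
        genes = [g.gene_id for g in annotation]
    else:
        genes = sorted(truth.activation_weights)
    samples, genotype_of_sample, mus = [], {}, []
    for gt in genotypes:
        retained = GENOTYPE_PIFS[gt]
        for r in range(config.n_bio_reps):
            name = f"{gt}_rep{r + 1}"
            samples.append(name)
            genotype_of_sample[name] = gt
            sf = (config.library_sizes or {}).get(name, 1.0)
            mu = np.array(
                [
                    sf
                    * (
                        config.baseline_mean
                        + sum(truth.activation_weights.get(g, {}).get(i, 0.0) for i in retained)
                    )
                    for g in genes
                ]
            )
            mus.append(mu)
    mu_mat = np.column_stack(mus)
    if config.dispersion == 0:
        counts = rng.poisson(mu_mat)
    else:
        r_shape = 1.0 / config.dispersion
        p = r_shape / (r_shape + mu_mat)
        counts = rng.negative_binomial(r_shape, p)
    df = pd.DataFrame(counts, index=pd.Index(genes, name="gene"), columns=samples)
    return CountMatrix(df, genotype_of_sample)
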