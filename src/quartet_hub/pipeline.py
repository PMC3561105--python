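"""End-to-end driver: peaks -> sites -> motifs -> genes -> DE -> classes.

``run_stages`` executes the chain on in-memory objects and returns every
intermediate plus a JSON-serializable report; ``run_pipeline`` wraps it
with file I/O from a :class:`RunConfig`.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from quartet_hub import io as qio
from quartet_hub.classify import (
    classify_targets,
    contribution_matrix,
    flag_yz15,
    share_decomposition,
)
from quartet_hub.de import (
    STANDARD_CONTRASTS,
    CountMatrix,
    build_composite_sets,
    estimate_common_dispersion,
    normalize,
    pairwise_de,
)
from quartet_hub.genes import GeneModel, assign_bound_genes, distance_bin_summary, is_intergenic
from quartet_hub.peaks import (
    DEFAULT_MOTIFS,
    PeakCall,
    annotate_coincidence,
    merge_replicate_peaks,
    motif_enrichment,
    scan_motifs,
)

log = logging.getLogger("quartet_hub")


@dataclass
class RunConfig:
    """Paths and stage parameters for a full pipeline run."""

    genome_fasta: str = ""
    annotation_gff: str = ""
    peak_files: list[str] = field(default_factory=list)
    counts_tsv: str = ""
    sample_map_tsv: str = ""
    out_dir: str = "quartet_hub_out"
    max_summit_distance: int = 100
    min_support: int = 2
    site_half_width: int = 100
    coincidence_distance: int = 100
    enrichment_widths: tuple[int, ...] = (201, 101, 51)
    n_simulations: int = 100
    gene_max_distance: int = 5000
    fc_threshold: float = 2.0
    alpha: float = 0.05
    yz15_threshold: float = 1.5
    seed: int = 0

    def validate(self) -> None:
        for name in (
            "max_summit_distance",
            "min_support",
            "coincidence_distance",
            "gene_max_distance",
            "fc_threshold",
            "alpha",
            "yz15_threshold",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if any(w % 2 == 0 for w in self.enrichment_widths):
            raise ValueError("enrichment widths must be odd so windows centre on summits")


def run_stages(
    genome: dict[str, str],
    annotation: list[GeneModel],
    peak_sets: list[list[PeakCall]],
    counts: CountMatrix,
    config: RunConfig | None = None,
) -> dict:
    """Execute every stage on in-memory inputs; returns intermediates and a report."""
    cfg = config or RunConfig()
    cfg.validate()
    path_fields = {"genome_fasta", "annotation_gff", "peak_files", "counts_tsv", "sample_map_tsv", "out_dir"}
    report: dict = {"parameters": {k: v for k, v in asdict(cfg).items() if k not in path_fields}}
    timings = {}

    def stage(name):
        timings[name] = time.perf_counter()
        log.info("stage %s", name)

    try:
        stage("merge")
        chrom_lengths = {c: len(s) for c, s in genome.items()}
        sites = merge_replicate_peaks(
            peak_sets,
            max_summit_distance=cfg.max_summit_distance,
            min_support=cfg.min_support,
            chrom_lengths=chrom_lengths,
            half_width=cfg.site_half_width,
        )

        stage("scan")
        hits_by_chrom = {c: scan_motifs(genome[c], DEFAULT_MOTIFS, chromosome=c) for c in genome}
        for s in sites:
            annotate_coincidence(
                s,
                hits_by_chrom.get(s.chromosome, []),
                max_distance=cfg.coincidence_distance,
                motif_ids=tuple(DEFAULT_MOTIFS),
            )

        stage("enrichment")
        enrichment = (
            motif_enrichment(
                sites,
                genome,
                DEFAULT_MOTIFS,
                widths=cfg.enrichment_widths,
                n_simulations=cfg.n_simulations,
                seed=cfg.seed,
            )
            if sites
            else []
        )

        stage("assignment")
        for s in sites:
            s.intergenic = is_intergenic(s, annotation)
        eligible = [s for s in sites if s.intergenic and s.coincident]
        bound = assign_bound_genes(eligible, annotation, max_distance=cfg.gene_max_distance)
        bound_ids = {b.gene_id for b in bound}

        stage("de")
        size_factors = normalize(counts.counts)
        phi = estimate_common_dispersion(counts.counts, counts.genotype_of_sample, size_factors)
        de_results = {
            c: pairwise_de(
                counts,
                c,
                phi=phi,
                size_factors=size_factors,
                fc_threshold=cfg.fc_threshold,
                alpha=cfg.alpha,
            )
            for c in STANDARD_CONTRASTS
        }

        stage("composite")
        sets = build_composite_sets(de_results)

        stage("classify")
        universe = sorted(set(counts.genes) | bound_ids)
        classifications = classify_targets(bound_ids, sets, universe)
        norm_counts = counts.counts / size_factors
        classifications = flag_yz15(
            classifications,
            norm_counts,
            counts.genotype_of_sample,
            threshold=cfg.yz15_threshold,
        )

        stage("contributions")
        genotypes = sorted(set(counts.genotype_of_sample.values()))
        mean_expr = pd.DataFrame(
            {gt: norm_counts[counts.samples_of(gt)].mean(axis=1) for gt in genotypes}
        )
        contributions = contribution_matrix(mean_expr) if "WT" in genotypes and "pifq" in genotypes else None
        shares = (
            share_decomposition(mean_expr)
            if {"WT", "pif145", "pifq"} <= set(genotypes)
            else None
        )
    except Exception as exc:
        failed = max(timings, key=timings.get) if timings else "setup"
        raise RuntimeError(f"pipeline stage {failed!r} failed: {exc}") from exc

    class_counts: dict[str, int] = {}
    for tc in classifications:
        class_counts[tc.target_class] = class_counts.get(tc.target_class, 0) + 1
    induced = {
        cls: sum(
            1 for tc in classifications if tc.target_class == cls and tc.direction == "PIF-induced"
        )
        for cls in ("X", "Y", "Z", "unbound-regulated")
    }
    report.update(
        {
            "n_sites": len(sites),
            "n_intergenic_sites": sum(1 for s in sites if s.intergenic),
            "n_eligible_sites": len(eligible),
            "n_bound_genes": len(bound_ids),
            "distance_bins": dict(zip(("<=3kb", "3-5kb"), distance_bin_summary(bound)))
            if bound
            else None,
            "dispersion": phi,
            "composite_set_sizes": {
                "quartet": len(sets.quartet_regulated),
                "pif3": len(sets.pif3_regulated),
                "trio145": len(sets.trio145_regulated),
            },
            "class_counts": class_counts,
            "class_counts_induced": induced,
            "yz15_genes": sorted(tc.gene_id for tc in classifications if tc.yz15),
            "enrichment": [
                {
                    "motif_id": r.motif_id,
                    "window_width": r.window_width,
                    "observed_fraction": r.observed_fraction,
                    "null_mean": r.null_mean,
                    "fold": r.fold,
                }
                for r in enrichment
            ],
        }
    )
    return {
        "report": report,
        "sites": sites,
        "enrichment": enrichment,
        "bound": bound,
        "size_factors": size_factors,
        "dispersion": phi,
        "de_results": de_results,
        "composite_sets": sets,
        "classifications": classifications,
        "mean_expression": mean_expr,
        "contributions": contributions,
        "shares": shares,
    }


def run_pipeline(config: RunConfig) -> dict:
    """File-based driver: read inputs, run every stage, write artifacts.

    Writes sites BED/TSV, enrichment TSV, bound-gene TSV, per-contrast DE
    TSVs, classification TSV, contribution TSV and a JSON run report to
    ``config.out_dir``; returns the report.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    genome = qio.read_fasta(config.genome_fasta)
    annotation = qio.read_gff3(config.annotation_gff)
    peak_sets = [
        qio.read_peaks(p, replicate_id=f"rep{i + 1}") for i, p in enumerate(config.peak_files)
    ]
    counts = qio.read_counts(config.counts_tsv, config.sample_map_tsv)

    res = run_stages(genome, annotation, peak_sets, counts, config)

    qio.write_sites(res["sites"], out / "sites.bed", out / "sites.tsv")
    if res["enrichment"]:
        qio.write_enrichment(res["enrichment"], out / "enrichment.tsv")
    qio.write_bound_genes(res["bound"], out / "bound_genes.tsv")
    for (a, b), de in res["de_results"].items():
        de.table.to_csv(out / f"de_{a}_vs_{b}.tsv", sep="\t")
    pd.DataFrame(
        [
            {
                "gene_id": tc.gene_id,
                "bound": tc.bound,
                "class": tc.target_class,
                "yz15": tc.yz15,
                "direction": tc.direction,
            }
            for tc in res["classifications"]
        ]
    ).to_csv(out / "classification.tsv", sep="\t", index=False)
    if res["contributions"] is not None:
        res["contributions"].to_csv(out / "contributions.tsv", sep="\t")
    if res["shares"] is not None:
        res["shares"].to_csv(out / "shares.tsv", sep="\t")
    with open(out / "report.json", "w") as fh:
        json.dump(res["report"], fh, indent=1, sort_keys=True, default=_json_default)
    return res["report"]


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, tuple):
        return list(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
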