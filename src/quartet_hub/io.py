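"""Readers and writers for the pipeline's file formats.

Internal coordinates are 1-based inclusive; BED and narrowPeak I/O convert
to and from 0-based half-open.  FASTA goes through Biopython; GFF3 gene
features are read with gffutils.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from quartet_hub.de import CountMatrix
from quartet_hub.genes import BoundGene, GeneModel
from quartet_hub.peaks import EnrichmentResult, PeakCall, ReproducibleSite


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(genome: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.items()]
    SeqIO.write(records, str(path), "fasta")


def read_gff3(path: str | Path) -> list[GeneModel]:
    """Read gene-type features (1-based inclusive) from a GFF3 file."""
    import gffutils

    db = gffutils.create_db(str(path), dbfn=":memory:", merge_strategy="create_unique")
    genes = []
    for feat in db.features_of_type("gene"):
        gene_id = feat.attributes.get("ID", [feat.id])[0]
        genes.append(GeneModel(gene_id, feat.seqid, feat.strand, feat.start, feat.end))
    genes.sort(key=lambda g: (g.chromosome, g.start, g.gene_id))
    return genes


def write_gff3(annotation: list[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in annotation:
            fh.write(
                f"{g.chromosome}\tquartet_hub\tgene\t{g.start}\t{g.end}\t.\t"
                f"{g.strand}\t.\tID={g.gene_id}\n"
            )


def read_peaks(path: str | Path, replicate_id: str) -> list[PeakCall]:
    """Read replicate peaks from BED6 or narrowPeak.

    For narrowPeak (10 columns) the summit is start + the column-10 offset
    when that offset is >= 0, else the interval midpoint; for BED6 the
    midpoint is used.  BED coordinates (0-based half-open) are converted to
    1-based.
    """
    peaks: list[PeakCall] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >= 3 BED fields")
            try:
                chrom, start, end = fields[0], int(fields[1]), int(fields[2])
                score = float(fields[4]) if len(fields) > 4 and fields[4] != "." else 0.0
                offset = int(fields[9]) if len(fields) >= 10 else -1
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            if offset >= 0:
                summit = start + offset + 1  # to 1-based
            else:
                summit = (start + end + 1) // 2  # midpoint, 1-based
            peaks.append(PeakCall(chrom, summit, score, replicate_id))
    return peaks


def write_peaks_narrowpeak(peaks: list[PeakCall], path: str | Path, half_width: int = 100) -> None:
    """Write peaks as narrowPeak point-summit intervals (0-based half-open)."""
    with open(path, "w") as fh:
        for i, p in enumerate(peaks, 1):
            start = max(0, p.summit - 1 - half_width)
            end = p.summit + half_width
            offset = p.summit - 1 - start
            fh.write(
                f"{p.chromosome}\t{start}\t{end}\tpeak_{i}\t{p.score:g}\t.\t0\t-1\t-1\t{offset}\n"
            )


def write_sites(sites: list[ReproducibleSite], bed_path: str | Path, tsv_path: str | Path) -> None:
    with open(bed_path, "w") as fh:
        for s in sites:
            fh.write(f"{s.chromosome}\t{s.interval[0] - 1}\t{s.interval[1]}\t{s.site_id}\t{s.support}\t.\n")
    rows = []
    for s in sites:
        row = {
            "site_id": s.site_id,
            "chromosome": s.chromosome,
            "mean_summit": s.mean_summit,
            "support": s.support,
            "truncated": s.truncated,
            "intergenic": s.intergenic,
        }
        for m, (flag, dist) in s.motif_flags.items():
            row[f"{m}_coincident"] = flag
            row[f"{m}_distance"] = dist
        rows.append(row)
    pd.DataFrame(rows).to_csv(tsv_path, sep="\t", index=False)


def write_enrichment(results: list[EnrichmentResult], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "motif_id": r.motif_id,
                "window_width": r.window_width,
                "observed_fraction": r.observed_fraction,
                "null_mean": r.null_mean,
                "null_sd": r.null_sd,
                "fold": r.fold if r.fold is not None else "undefined",
                "n_simulations": r.n_simulations,
            }
            for r in results
        ]
    ).to_csv(path, sep="\t", index=False)


def write_bound_genes(bound: list[BoundGene], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "gene_id": b.gene_id,
                "site_id": b.site_id,
                "distance_to_tss": b.distance_to_tss,
                "distance_bin": b.distance_bin,
            }
            for b in bound
        ]
    ).to_csv(path, sep="\t", index=False)


def read_counts(counts_path: str | Path, sample_map_path: str | Path) -> CountMatrix:
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    counts.index.name = "gene"
    sample_map = pd.read_csv(sample_map_path, sep="\t")
    if list(sample_map.columns[:2]) != ["sample", "genotype"]:
        raise ValueError("sample map must have columns: sample, genotype")
    genotype_of_sample = dict(zip(sample_map["sample"], sample_map["genotype"]))
    return CountMatrix(counts.astype(int), genotype_of_sample)


def write_counts(cm: CountMatrix, counts_path: str | Path, sample_map_path: str | Path) -> None:
    cm.counts.to_csv(counts_path, sep="\t")
    pd.DataFrame(
        {"sample": list(cm.counts.columns), "genotype": [cm.genotype_of_sample[s] for s in cm.counts.columns]}
    ).to_csv(sample_map_path, sep="\t", index=False)


def write_ground_truth(truth, path: str | Path) -> None:
    payload = {
        "sites": [
            {"chromosome": s.chromosome, "summit": s.summit, "gene_id": s.gene_id, "motif_id": s.motif_id}
            for s in truth.sites
        ],
        "true_target_map": {str(k): v for k, v in truth.true_target_map.items()},
        "activation_weights": {
            g: {str(i): a for i, a in w.items()} for g, w in truth.activation_weights.items()
        },
        "planted_contributions": {
            g: {str(i): c for i, c in w.items()} for g, w in truth.planted_contributions.items()
        },
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
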