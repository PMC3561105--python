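"""Promoter assignment of binding sites to candidate target genes.

A site is intergenic when its mean summit falls inside no annotated gene
span.  Intergenic, motif-coincident sites are assigned to genes through the
promoter rule: the nearest gene on each strand whose TSS lies downstream of
the summit in that gene's sense orientation, within 5 kb, with no other
gene's span or TSS intersecting the open interval between summit and TSS.
A single site may serve a divergent gene pair and yield two assignments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from quartet_hub.peaks import ReproducibleSite


@dataclass(frozen=True)
class GeneModel:
    """A stranded gene span (1-based inclusive); the TSS is the start for
    '+' genes and the end for '-' genes."""

    gene_id: str
    chromosome: str
    strand: str
    start: int
    end: int

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start > end")
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: bad strand {self.strand!r}")

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end


@dataclass(frozen=True)
class BoundGene:
    gene_id: str
    site_id: str
    distance_to_tss: int  # bp > 0 along the gene's upstream direction
    distance_bin: str  # "<=3kb" or "3-5kb"


def is_intergenic(site: ReproducibleSite, annotation: list[GeneModel]) -> bool:
    """True iff the mean summit lies inside no gene span (either strand)."""
    return not any(
        g.chromosome == site.chromosome and g.start <= site.mean_summit <= g.end
        for g in annotation
    )


def _blocked(summit: int, tss: int, candidate: GeneModel, annotation: list[GeneModel]) -> bool:
    """Whether any other gene's span or TSS intersects the open interval
    (summit, tss)."""
    lo, hi = min(summit, tss), max(summit, tss)
    for g in annotation:
        if g.gene_id == candidate.gene_id or g.chromosome != candidate.chromosome:
            continue
        if g.start < hi and g.end > lo:  # span overlaps the open interval
            return True
        if lo < g.tss < hi:
            return True
    return False


def _distance_bin(d: int) -> str:
    return "<=3kb" if d <= 3000 else "3-5kb"


def assign_bound_genes(
    sites: list[ReproducibleSite],
    annotation: list[GeneModel],
    max_distance: int = 5000,
    require_filters: bool = True,
) -> list[BoundGene]:
    """Assign intergenic, motif-coincident sites to candidate target genes.

    For each site and each strand the nearest gene whose TSS is downstream
    of the summit in the gene's sense orientation (0 < distance <=
    ``max_distance``) is assigned, unless another gene's span or TSS
    intersects the open summit-TSS interval.  Sites failing the intergenic
    or coincidence precondition are skipped with a warning when
    ``require_filters`` is set.
    """
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in annotation:
        by_chrom.setdefault(g.chromosome, []).append(g)
    out: list[BoundGene] = []
    for site in sites:
        if require_filters:
            if site.motif_flags and not site.coincident:
                warnings.warn(f"{site.site_id}: not motif-coincident, skipped")
                continue
            if not is_intergenic(site, annotation):
                warnings.warn(f"{site.site_id}: summit inside a gene, skipped")
                continue
        genes = by_chrom.get(site.chromosome, [])
        for strand in "+-":
            candidates = []
            for g in genes:
                if g.strand != strand:
                    continue
                d = g.tss - site.mean_summit if strand == "+" else site.mean_summit - g.tss
                if 0 < d <= max_distance:
                    candidates.append((d, g))
            if not candidates:
                continue
            d, nearest = min(candidates, key=lambda t: (t[0], t[1].gene_id))
            if not _blocked(site.mean_summit, nearest.tss, nearest, genes):
                out.append(BoundGene(nearest.gene_id, site.site_id, d, _distance_bin(d)))
    out.sort(key=lambda b: (b.gene_id, b.site_id))
    return out


def distance_bin_summary(bound: list[BoundGene]) -> tuple[float, float]:
    """Fractions of assignments with distance <= 3 kb and in (3 kb, 5 kb]."""
    if not bound:
        raise ValueError("empty bound-gene list")
    near = sum(1 for b in bound if b.distance_to_tss <= 3000)
    return near / len(bound), (len(bound) - near) / len(bound)
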