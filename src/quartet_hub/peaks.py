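"""Reproducible ChIP binding sites and consensus-motif analysis.

Replicate-specific peak summits are clustered into reproducible sites
(support from >= 2 replicates, summits within 100 bp), each represented by
a 201-bp window centred on the rounded mean summit.  Sites are annotated
with G-box / PBE-box coincidence (nearest motif centre within 100 bp of the
summit) and motif enrichment is measured against randomly placed genomic
windows of the same width.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

G_BOX = "CACGTG"
PBE_BOX = "CACATG"
DEFAULT_MOTIFS: dict[str, str] = {"G-box": G_BOX, "PBE-box": PBE_BOX}

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class PeakCall:
    """A single replicate-specific peak summit (1-based coordinate)."""

    chromosome: str
    summit: int
    score: float
    replicate_id: str


@dataclass
class MotifHit:
    """One consensus-motif occurrence; ``center`` is the fixed integer proxy
    start + 2 (third base of the 6-mer)."""

    motif_id: str
    chromosome: str
    start: int  # 1-based
    strand: str

    @property
    def center(self) -> int:
        return self.start + 2


@dataclass
class ReproducibleSite:
    """A binding site supported by summits from >= 2 replicates."""

    site_id: str
    chromosome: str
    mean_summit: int
    support: int
    member_summits: list[int]
    member_replicates: list[str]
    interval: tuple[int, int]  # 1-based inclusive, 201 bp unless truncated
    truncated: bool = False
    # per motif_id: (coincident, distance or None)
    motif_flags: dict[str, tuple[bool, int | None]] = field(default_factory=dict)
    intergenic: bool | None = None

    @property
    def coincident(self) -> bool:
        return any(flag for flag, _ in self.motif_flags.values())


@dataclass
class EnrichmentResult:
    motif_id: str
    window_width: int
    observed_fraction: float
    null_mean: float
    null_sd: float
    fold: float | None  # None flags an undefined fold (null_mean == 0)
    n_simulations: int


def _round_half_down(x: float) -> int:
    """Round to the nearest integer, ties toward the lower coordinate."""
    return math.ceil(x - 0.5)


def merge_replicate_peaks(
    peak_sets: list[list[PeakCall]],
    max_summit_distance: int = 100,
    min_support: int = 2,
    chrom_lengths: dict[str, int] | None = None,
    half_width: int = 100,
) -> list[ReproducibleSite]:
    """Cluster replicate peak summits into reproducible binding sites.

    Seed-and-absorb clustering: all peaks are ordered by descending score
    (ties broken by chromosome, coordinate, then replicate id); the
    highest-scoring unassigned peak seeds a site and absorbs, from each
    other replicate, the nearest unassigned summit on the same chromosome
    within ``max_summit_distance`` of the seed (at most one per replicate).
    Clusters supported by fewer than ``min_support`` distinct replicates
    are dropped, but their peaks stay consumed.

    The mean summit is the arithmetic mean of member summits rounded half
    down; the site interval is the (2*half_width + 1)-bp window centred on
    it, truncated (and flagged) only at chromosome ends.
    """
    if len(peak_sets) < 2:
        raise ValueError("at least two replicate peak sets are required")

    peaks: list[PeakCall] = [p for ps in peak_sets for p in ps]
    order = sorted(
        range(len(peaks)),
        key=lambda i: (-peaks[i].score, peaks[i].chromosome, peaks[i].summit, peaks[i].replicate_id),
    )
    assigned = [False] * len(peaks)
    # per (replicate, chromosome): sorted index lists for nearest lookup
    sites: list[ReproducibleSite] = []
    n_site = 0
    replicate_ids = sorted({p.replicate_id for p in peaks})

    by_rep_chrom: dict[tuple[str, str], list[int]] = {}
    for i, p in enumerate(peaks):
        by_rep_chrom.setdefault((p.replicate_id, p.chromosome), []).append(i)
    for idxs in by_rep_chrom.values():
        idxs.sort(key=lambda i: (peaks[i].summit, peaks[i].replicate_id))

    for seed_idx in order:
        if assigned[seed_idx]:
            continue
        seed = peaks[seed_idx]
        assigned[seed_idx] = True
        members = [seed_idx]
        for rep in replicate_ids:
            if rep == seed.replicate_id:
                continue
            cands = by_rep_chrom.get((rep, seed.chromosome), [])
            best = None
            best_key = None
            for i in cands:
                if assigned[i]:
                    continue
                d = abs(peaks[i].summit - seed.summit)
                if d < max_summit_distance:
                    key = (d, peaks[i].summit)  # ties: lower coordinate
                    if best is None or key < best_key:
                        best, best_key = i, key
            if best is not None:
                assigned[best] = True
                members.append(best)
        support = len({peaks[i].replicate_id for i in members})
        if support < min_support:
            continue
        summits = sorted(peaks[i].summit for i in members)
        mean_summit = _round_half_down(sum(summits) / len(summits))
        lo, hi = mean_summit - half_width, mean_summit + half_width
        truncated = False
        if lo < 1:
            lo, truncated = 1, True
        if chrom_lengths is not None and hi > chrom_lengths[seed.chromosome]:
            hi, truncated = chrom_lengths[seed.chromosome], True
        n_site += 1
        sites.append(
            ReproducibleSite(
                site_id=f"site_{n_site}",
                chromosome=seed.chromosome,
                mean_summit=mean_summit,
                support=support,
                member_summits=summits,
                member_replicates=sorted(peaks[i].replicate_id for i in members),
                interval=(lo, hi),
                truncated=truncated,
            )
        )
    sites.sort(key=lambda s: (s.chromosome, s.mean_summit, s.site_id))
    for k, s in enumerate(sites, 1):
        s.site_id = f"site_{k}"
    return sites


def scan_motifs(
    sequence: str,
    motifs: dict[str, str] | None = None,
    chromosome: str = "chr",
) -> list[MotifHit]:
    """Report every consensus occurrence on either strand.

    A palindromic consensus (e.g. the G-box) is reported once per position
    with strand '+'.  A non-palindromic consensus matching on the minus
    strand appears in the forward text as its reverse complement and is
    reported with strand '-'.  Positions containing N never match.
    """
    if motifs is None:
        motifs = DEFAULT_MOTIFS
    seq = sequence.upper()
    hits: list[MotifHit] = []
    for motif_id, consensus in motifs.items():
        consensus = consensus.upper()
        rc = reverse_complement(consensus)
        patterns = [(consensus, "+")]
        if rc != consensus:
            patterns.append((rc, "-"))
        for pattern, strand in patterns:
            start = seq.find(pattern)
            while start != -1:
                hits.append(MotifHit(motif_id, chromosome, start + 1, strand))
                start = seq.find(pattern, start + 1)
    hits.sort(key=lambda h: (h.chromosome, h.start, h.motif_id, h.strand))
    return hits


def annotate_coincidence(
    site: ReproducibleSite,
    hits: list[MotifHit],
    max_distance: int = 100,
    motif_ids: tuple[str, ...] | None = None,
) -> ReproducibleSite:
    """Flag each motif as coincident when the nearest hit centre is strictly
    within ``max_distance`` of the mean summit; the minimizing distance is
    stored for coincident motifs."""
    if motif_ids is None:
        motif_ids = tuple(sorted({h.motif_id for h in hits})) or tuple(DEFAULT_MOTIFS)
    for motif_id in motif_ids:
        dists = [
            abs(h.center - site.mean_summit)
            for h in hits
            if h.motif_id == motif_id and h.chromosome == site.chromosome
        ]
        best = min(dists) if dists else None
        if best is not None and best < max_distance:
            site.motif_flags[motif_id] = (True, best)
        else:
            site.motif_flags[motif_id] = (False, None)
    return site


def _window_contains(seq_window: str, consensus: str) -> bool:
    rc = reverse_complement(consensus)
    return consensus in seq_window or (rc != consensus and rc in seq_window)


def motif_enrichment(
    sites: list[ReproducibleSite],
    genome: dict[str, str],
    motifs: dict[str, str] | None = None,
    widths: tuple[int, ...] = (201, 101, 51),
    n_simulations: int = 100,
    seed: int | np.random.Generator = 0,
) -> list[EnrichmentResult]:
    """Permutation enrichment of each motif in windows centred on summits.

    For each motif x width the observed fraction of site windows containing
    at least one occurrence is compared with the mean fraction over
    ``n_simulations`` draws of ``len(sites)`` uniform-random genomic windows
    of the same width (fully inside chromosomes; random windows may overlap
    each other and real sites).  ``fold`` is observed/null_mean, flagged
    undefined (None) when the null mean is zero.
    """
    if not sites:
        raise ValueError("at least one site is required")
    if motifs is None:
        motifs = DEFAULT_MOTIFS
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    chroms = sorted(genome)
    seqs = {c: genome[c].upper() for c in chroms}
    results: list[EnrichmentResult] = []
    for width in widths:
        half = width // 2
        valid_starts = np.array([len(seqs[c]) - width + 1 for c in chroms])
        if np.any(valid_starts < 1):
            raise ValueError(f"width {width} exceeds the smallest chromosome")
        probs = valid_starts / valid_starts.sum()
        observed: dict[str, int] = {m: 0 for m in motifs}
        for s in sites:
            lo = max(0, s.mean_summit - 1 - half)
            window = seqs[s.chromosome][lo : s.mean_summit - 1 + half + 1]
            for m, consensus in motifs.items():
                if _window_contains(window, consensus):
                    observed[m] += 1
        null_fracs: dict[str, list[float]] = {m: [] for m in motifs}
        for _ in range(n_simulations):
            counts = {m: 0 for m in motifs}
            chrom_idx = rng.choice(len(chroms), size=len(sites), p=probs)
            for ci in chrom_idx:
                c = chroms[ci]
                start = int(rng.integers(0, valid_starts[ci]))
                window = seqs[c][start : start + width]
                for m, consensus in motifs.items():
                    if _window_contains(window, consensus):
                        counts[m] += 1
            for m in motifs:
                null_fracs[m].append(counts[m] / len(sites))
        for m in motifs:
            obs = observed[m] / len(sites)
            nm = float(np.mean(null_fracs[m]))
            nsd = float(np.std(null_fracs[m], ddof=1)) if n_simulations > 1 else 0.0
            fold = obs / nm if nm > 0 else None
            results.append(EnrichmentResult(m, width, obs, nm, nsd, fold, n_simulations))
    return results


def motif_position_histogram(
    sites: list[ReproducibleSite],
    hits: list[MotifHit],
    flank: int = 500,
    bin_size: int = 25,
    site_half_width: int = 100,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Histogram of motif centres by signed offset from the mean summit.

    Returns ``(bin_edges, counts, within_site_fraction)`` where the fraction
    is the share of hits within +/- flank whose offset also falls inside the
    201-bp site window (|offset| <= site_half_width).
    """
    if flank <= 0:
        raise ValueError("flank must be positive")
    hits_by_chrom: dict[str, list[int]] = {}
    for h in hits:
        hits_by_chrom.setdefault(h.chromosome, []).append(h.center)
    offsets: list[int] = []
    for s in sites:
        for center in hits_by_chrom.get(s.chromosome, []):
            off = center - s.mean_summit
            if -flank <= off <= flank:
                offsets.append(off)
    edges = np.arange(-flank, flank + bin_size, bin_size)
    counts, edges = np.histogram(offsets, bins=edges)
    if offsets:
        within = sum(1 for o in offsets if abs(o) <= site_half_width) / len(offsets)
    else:
        within = float("nan")
    return edges, counts, within
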