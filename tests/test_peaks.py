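"""Reproducible-site merging, motif scanning, coincidence and enrichment."""

import numpy as np
import pytest

from quartet_hub.peaks import (
    DEFAULT_MOTIFS,
    EnrichmentResult,
    MotifHit,
    PeakCall,
    ReproducibleSite,
    annotate_coincidence,
    merge_replicate_peaks,
    motif_enrichment,
    motif_position_histogram,
    reverse_complement,
    scan_motifs,
)


def make_site(summit, chromosome="chr1", site_id="s1"):
    return ReproducibleSite(
        site_id, chromosome, summit, 2, [summit], ["rep1", "rep2"], (summit - 100, summit + 100)
    )


# ---------------------------------------------------------------- merging


def oracle_merge(peak_sets, max_dist=100, min_support=2):
    """Independent brute-force clustering with the same seed-ordering rule:
    repeatedly pick the unassigned peak with the highest score (ties by
    chromosome, coordinate, replicate), then from every other replicate
    take the nearest unassigned summit strictly within max_dist."""
    peaks = [p for ps in peak_sets for p in ps]
    unassigned = set(range(len(peaks)))
    clusters = []
    while unassigned:
        seed = min(
            unassigned,
            key=lambda i: (-peaks[i].score, peaks[i].chromosome, peaks[i].summit, peaks[i].replicate_id),
        )
        unassigned.discard(seed)
        members = [seed]
        for rep in sorted({p.replicate_id for p in peaks}):
            if rep == peaks[seed].replicate_id:
                continue
            cands = [
                i
                for i in unassigned
                if peaks[i].replicate_id == rep
                and peaks[i].chromosome == peaks[seed].chromosome
                and abs(peaks[i].summit - peaks[seed].summit) < max_dist
            ]
            if cands:
                best = min(cands, key=lambda i: (abs(peaks[i].summit - peaks[seed].summit), peaks[i].summit))
                unassigned.discard(best)
                members.append(best)
        if len({peaks[i].replicate_id for i in members}) >= min_support:
            clusters.append(sorted(peaks[i].summit for i in members))
    return sorted(clusters)


def random_peak_sets(rng, n_reps=4, n_peaks=50, chrom_len=100_000):
    return [
        [
            PeakCall("chr1", int(rng.integers(1, chrom_len + 1)), float(rng.uniform(0, 100)), f"rep{r + 1}")
            for _ in range(n_peaks)
        ]
        for r in range(n_reps)
    ]


def test_merge_two_summits_within_threshold():
    sets = [
        [PeakCall("chr1", 1000, 5.0, "A")],
        [PeakCall("chr1", 1050, 4.0, "B")],
    ]
    (site,) = merge_replicate_peaks(sets)
    assert site.mean_summit == 1025
    assert site.support == 2
    assert site.interval == (925, 1125)
    assert not site.truncated


def test_merge_requires_two_replicates_and_respects_distance():
    with pytest.raises(ValueError):
        merge_replicate_peaks([[PeakCall("chr1", 1000, 5.0, "A")]])
    sets = [
        [PeakCall("chr1", 1000, 5.0, "A")],
        [PeakCall("chr1", 1200, 4.0, "B")],
    ]
    assert merge_replicate_peaks(sets) == []


def test_merge_never_groups_across_chromosomes():
    sets = [
        [PeakCall("chr1", 1000, 5.0, "A")],
        [PeakCall("chr2", 1000, 4.0, "B")],
    ]
    assert merge_replicate_peaks(sets) == []


def test_merge_mean_rounding_is_half_down():
    sets = [
        [PeakCall("chr1", 1000, 5.0, "A")],
        [PeakCall("chr1", 1001, 4.0, "B")],
    ]
    (site,) = merge_replicate_peaks(sets)
    assert site.mean_summit == 1000  # 1000.5 rounds toward the lower coordinate


def test_merge_matches_brute_force_oracle():
    rng = np.random.default_rng(42)
    for _ in range(5):
        sets = random_peak_sets(rng)
        sites = merge_replicate_peaks(sets)
        got = sorted(s.member_summits for s in sites)
        assert got == oracle_merge(sets)


def test_merge_is_invariant_to_input_order():
    rng = np.random.default_rng(1)
    sets = random_peak_sets(rng, n_peaks=30)
    ref = [(s.chromosome, s.mean_summit, tuple(s.member_summits)) for s in merge_replicate_peaks(sets)]
    for perm_seed in range(3):
        prng = np.random.default_rng(perm_seed)
        shuffled = [list(prng.permutation(np.array(ps, dtype=object))) for ps in sets]
        shuffled = [shuffled[i] for i in prng.permutation(len(shuffled))]
        got = [
            (s.chromosome, s.mean_summit, tuple(s.member_summits))
            for s in merge_replicate_peaks(shuffled)
        ]
        assert got == ref


def test_merged_sites_have_distinct_replicates():
    rng = np.random.default_rng(9)
    sets = random_peak_sets(rng, n_peaks=80, chrom_len=50_000)
    for site in merge_replicate_peaks(sets):
        assert site.support == len(set(site.member_replicates))
        assert site.support >= 2


# ---------------------------------------------------------------- motif scan


def oracle_scan(seq, motifs):
    """Naive 6-mer sliding window over both strands."""
    hits = set()
    seq = seq.upper()
    for motif_id, consensus in motifs.items():
        k = len(consensus)
        rc = reverse_complement(consensus)
        for i in range(len(seq) - k + 1):
            word = seq[i : i + k]
            if word == consensus:
                hits.add((motif_id, i + 1, "+"))
            elif word == rc and rc != consensus:
                hits.add((motif_id, i + 1, "-"))
    return hits


def test_gbox_forward_match():
    (hit,) = scan_motifs("AACACGTGTT", {"G-box": "CACGTG"})
    assert (hit.start, hit.strand) == (3, "+")
    assert hit.center == 5


def test_pbe_reverse_complement_match():
    (hit,) = scan_motifs("AACATGTGTT", {"PBE-box": "CACATG"})
    assert (hit.start, hit.strand) == (3, "-")


def test_palindrome_reported_once_and_n_never_matches():
    assert len(scan_motifs("CACGTG", {"G-box": "CACGTG"})) == 1
    assert scan_motifs("CACNTG", DEFAULT_MOTIFS) == []
    assert scan_motifs("ACGT", DEFAULT_MOTIFS) == []


def test_scan_matches_naive_oracle_on_random_sequence():
    rng = np.random.default_rng(0)
    seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=10_000)])
    got = {(h.motif_id, h.start, h.strand) for h in scan_motifs(seq, DEFAULT_MOTIFS)}
    assert got == oracle_scan(seq, DEFAULT_MOTIFS)


# ---------------------------------------------------------------- coincidence


def test_coincidence_distance_is_strict():
    site = make_site(1000)
    hits = [MotifHit("G-box", "chr1", 1048, "+")]  # center 1050
    annotate_coincidence(site, hits)
    assert site.motif_flags["G-box"] == (True, 50)
    site2 = make_site(1000)
    annotate_coincidence(site2, [MotifHit("G-box", "chr1", 1098, "+")])  # center 1100
    assert site2.motif_flags["G-box"] == (False, None)


def test_coincidence_matches_brute_force_nearest_hit():
    rng = np.random.default_rng(3)
    hits = [
        MotifHit(m, "chr1", int(rng.integers(1, 5000)), "+")
        for m in DEFAULT_MOTIFS
        for _ in range(10)
    ]
    for _ in range(20):
        summit = int(rng.integers(1, 5000))
        site = annotate_coincidence(make_site(summit), hits, motif_ids=tuple(DEFAULT_MOTIFS))
        for m in DEFAULT_MOTIFS:
            dists = [abs(h.center - summit) for h in hits if h.motif_id == m]
            best = min(dists)
            assert site.motif_flags[m] == ((best < 100), best if best < 100 else None)


# ---------------------------------------------------------------- enrichment


def test_enrichment_degenerate_null_is_flagged_undefined():
    # poly-A genome except a G-box planted at each site summit; the genome
    # is large enough that the seeded null draws never land on a motif
    seq = ["A"] * 200_000
    summits = [5_000, 55_000, 105_000, 155_000]
    for s in summits:
        seq[s - 3 : s + 3] = list("CACGTG")
    genome = {"chr1": "".join(seq)}
    sites = [make_site(s, site_id=f"s{i}") for i, s in enumerate(summits)]
    results = motif_enrichment(sites, genome, {"G-box": "CACGTG"}, widths=(51,), n_simulations=30, seed=0)
    (r,) = results
    assert r.observed_fraction == 1.0
    assert r.null_mean == pytest.approx(0.0)
    assert r.fold is None


def test_enrichment_is_unity_for_random_sites():
    rng = np.random.default_rng(12)
    seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=60_000)])
    genome = {"chr1": seq}
    sites = [
        make_site(int(rng.integers(150, len(seq) - 150)), site_id=f"s{i}") for i in range(120)
    ]
    for r in motif_enrichment(sites, genome, DEFAULT_MOTIFS, n_simulations=60, seed=1):
        assert r.null_mean > 0
        se = r.null_sd / np.sqrt(len(sites)) if r.null_sd else 0.05
        assert abs(r.fold - 1.0) <= 3 * max(r.null_sd / r.null_mean, 0.05), r


def test_enrichment_null_matches_exhaustive_enumeration():
    rng = np.random.default_rng(8)
    seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=2000)])
    genome = {"chr1": seq}
    width = 51
    # exact probability that a random width-bp window contains the motif
    contains = 0
    total = len(seq) - width + 1
    from quartet_hub.peaks import _window_contains

    for start in range(total):
        if _window_contains(seq[start : start + width], "CACGTG"):
            contains += 1
    exact = contains / total
    sites = [make_site(int(rng.integers(100, 1900)), site_id=f"s{i}") for i in range(30)]
    (r,) = motif_enrichment(sites, genome, {"G-box": "CACGTG"}, widths=(width,), n_simulations=200, seed=2)
    se = np.sqrt(exact * (1 - exact) / (len(sites) * 200))
    assert abs(r.null_mean - exact) <= max(2 * se, 0.02)


def test_enrichment_rejects_oversized_windows():
    with pytest.raises(ValueError):
        motif_enrichment([make_site(100)], {"chr1": "ACGT" * 50}, widths=(501,), n_simulations=5, seed=0)


# ---------------------------------------------------------------- histogram


def test_histogram_central_bin_and_within_site_fraction():
    sites = [make_site(1000), make_site(3000, site_id="s2")]
    hits = [MotifHit("G-box", "chr1", s - 2, "+") for s in (1000, 3000)]  # centers at summits
    edges, counts, within = motif_position_histogram(sites, hits, flank=500, bin_size=25)
    assert counts.sum() == 2
    central = np.nonzero(counts)[0]
    assert len(central) == 1
    assert edges[central[0]] <= 0 < edges[central[0] + 1]
    assert within == 1.0


def test_histogram_empty_when_no_hits_in_flank():
    sites = [make_site(1000)]
    hits = [MotifHit("G-box", "chr1", 5000, "+")]
    _, counts, within = motif_position_histogram(sites, hits, flank=500)
    assert counts.sum() == 0
    assert np.isnan(within)


def test_histogram_matches_direct_recount():
    rng = np.random.default_rng(4)
    sites = [make_site(int(rng.integers(600, 9400)), site_id=f"s{i}") for i in range(10)]
    hits = [MotifHit("G-box", "chr1", int(rng.integers(1, 10_000)), "+") for _ in range(200)]
    edges, counts, within = motif_position_histogram(sites, hits, flank=500, bin_size=25)
    offsets = [
        h.center - s.mean_summit
        for s in sites
        for h in hits
        if -500 <= h.center - s.mean_summit <= 500
    ]
    expected, _ = np.histogram(offsets, bins=edges)
    assert (counts == expected).all()
    assert within == pytest.approx(sum(1 for o in offsets if abs(o) <= 100) / len(offsets))


# ---------------------------------------------------------------- properties

from hypothesis import given, settings
from hypothesis import strategies as st


@settings(max_examples=60, derandomize=True, deadline=None)
@given(st.text(alphabet="ACGTN", min_size=0, max_size=80))
def test_scan_always_matches_naive_oracle(seq):
    """Consensus scanning equals the sliding-window oracle for any sequence,
    including ones containing N."""
    got = {(h.motif_id, h.start, h.strand) for h in scan_motifs(seq, DEFAULT_MOTIFS)}
    assert got == oracle_scan(seq, DEFAULT_MOTIFS)
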