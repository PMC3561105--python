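"""Negative-binomial differential expression and SSTF gene sets.

Statistically-Significant Two-Fold (SSTF) genes are those whose normalized
expression differs >= 2-fold between two genotypes with a
Benjamini-Hochberg adjusted P <= 0.05.  The test is a self-contained NB
exact test: median-of-ratios size factors, a method-of-moments common
dispersion, and a conditional exact test on the group totals.  Composite
regulated gene sets combine a loss-of-function contrast (mutant vs WT) with
the matching gain-of-function contrast (quadruple vs triple mutant).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

#: PIF-quartet members retained in each genotype.
GENOTYPE_PIFS: dict[str, frozenset[int]] = {
    "WT": frozenset({1, 3, 4, 5}),
    "pif3": frozenset({1, 4, 5}),
    "pif145": frozenset({3}),
    "pifq": frozenset(),
    "pif134": frozenset({5}),
    "pif135": frozenset({4}),
    "pif345": frozenset({1}),
}

#: In each standard contrast (A, B), A is the more-mutant genotype, so a
#: negative log2FC(A/B) means the missing PIF(s) normally induce the gene.
STANDARD_CONTRASTS = [
    ("pif3", "WT"),
    ("pif145", "WT"),
    ("pifq", "WT"),
    ("pifq", "pif145"),
    ("pifq", "pif3"),
]


@dataclass
class CountMatrix:
    """Gene x sample integer counts with a sample -> genotype map."""

    counts: pd.DataFrame  # genes x samples
    genotype_of_sample: dict[str, str]

    def __post_init__(self):
        if (self.counts.values < 0).any():
            raise ValueError("counts must be nonnegative")
        missing = set(self.counts.columns) - set(self.genotype_of_sample)
        if missing:
            raise ValueError(f"samples without genotype label: {sorted(missing)}")

    @property
    def genes(self) -> list[str]:
        return list(self.counts.index)

    def samples_of(self, genotype: str) -> list[str]:
        return [s for s in self.counts.columns if self.genotype_of_sample[s] == genotype]


@dataclass
class PairwiseDE:
    contrast: tuple[str, str]
    table: pd.DataFrame  # index gene; log2fc, pvalue, padj, sstf, direction


@dataclass
class CompositeSets:
    quartet_regulated: set[str]
    pif3_regulated: set[str]
    trio145_regulated: set[str]
    # per composite set, gene -> "PIF-induced" | "PIF-repressed" | "ambiguous"
    direction: dict[str, dict[str, str]] = field(default_factory=dict)


def normalize(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors, scaled to geometric mean 1.

    The reference is the per-gene geometric mean over genes positive in all
    samples; if no such gene exists, total-count factors are used with a
    warning.
    """
    mat = counts.to_numpy(dtype=float)
    all_pos = (mat > 0).all(axis=1)
    if all_pos.any():
        logref = np.log(mat[all_pos]).mean(axis=1)
        ratios = np.log(mat[all_pos]) - logref[:, None]
        logsf = np.median(ratios, axis=0)
    else:
        warnings.warn("no gene positive in all samples; using total-count factors")
        totals = mat.sum(axis=0)
        if (totals == 0).any():
            raise ValueError("sample with zero total counts")
        logsf = np.log(totals)
    logsf = logsf - logsf.mean()  # geometric mean 1
    return pd.Series(np.exp(logsf), index=counts.columns, name="size_factor")


def estimate_common_dispersion(
    counts: pd.DataFrame,
    genotype_of_sample: dict[str, str],
    size_factors: pd.Series | None = None,
    mean_floor: float = 5.0,
) -> float:
    """Method-of-moments common NB dispersion.

    Per gene x genotype (>= 2 replicates) on normalized counts:
    phi = max(0, (s^2 - m) / m^2); the common value is the median over
    entries whose mean exceeds ``mean_floor``.
    """
    if size_factors is None:
        size_factors = normalize(counts)
    norm = counts / size_factors
    groups = {}
    for s, g in genotype_of_sample.items():
        if s in counts.columns:
            groups.setdefault(g, []).append(s)
    groups = {g: ss for g, ss in groups.items() if len(ss) >= 2}
    if not groups:
        raise ValueError("no genotype with >= 2 replicates")
    phis = []
    for ss in groups.values():
        sub = norm[ss].to_numpy()
        m = sub.mean(axis=1)
        v = sub.var(axis=1, ddof=1)
        ok = m > mean_floor
        phis.append(np.maximum(0.0, (v[ok] - m[ok]) / m[ok] ** 2))
    phis = np.concatenate(phis)
    if phis.size == 0:
        return 0.0
    return float(np.median(phis))


def _cond_logpmf(t: int, r_a: float, r_b: float) -> np.ndarray:
    """Log pmf of the split a | a+b = t for independent NB(r_a, p), NB(r_b, p)
    with a common success probability (negative hypergeometric); the shared
    p cancels, so the distribution depends only on the shape parameters."""
    a = np.arange(t + 1)
    logw = (
        gammaln(a + r_a)
        - gammaln(a + 1)
        + gammaln(t - a + r_b)
        - gammaln(t - a + 1)
    )
    return logw - logsumexp(logw)


def nb_exact_test(
    counts_a: np.ndarray,
    counts_b: np.ndarray,
    phi: float,
    size_factors_a: np.ndarray | None = None,
    size_factors_b: np.ndarray | None = None,
) -> float:
    """Two-sided conditional exact test for one gene.

    Normalized counts are summed per group and rounded; conditional on the
    total t, the split follows a negative hypergeometric law with shapes
    n_g / phi (sum of n_g iid NB(mu, phi) variables).  The p-value sums the
    probabilities of all splits no more likely than the observed one.  At
    phi = 0 the conditional law is Binomial(t, n_a / (n_a + n_b)).
    """
    counts_a = np.asarray(counts_a, dtype=float)
    counts_b = np.asarray(counts_b, dtype=float)
    if size_factors_a is not None:
        counts_a = counts_a / np.asarray(size_factors_a, dtype=float)
    if size_factors_b is not None:
        counts_b = counts_b / np.asarray(size_factors_b, dtype=float)
    ya = int(round(counts_a.sum()))
    yb = int(round(counts_b.sum()))
    t = ya + yb
    if t == 0:
        return 1.0
    na, nb = len(counts_a), len(counts_b)
    if phi < 0:
        raise ValueError("dispersion must be nonnegative")
    if phi == 0:
        from scipy.stats import binom

        logp = binom.logpmf(np.arange(t + 1), t, na / (na + nb))
    else:
        logp = _cond_logpmf(t, na / phi, nb / phi)
    obs = logp[ya]
    p = float(np.exp(logsumexp(logp[logp <= obs + 1e-10])))
    return min(1.0, p)


def bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, clipped at 1."""
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def call_sstf(log2fc: np.ndarray, adj_p: np.ndarray, fc_threshold: float = 2.0, alpha: float = 0.05):
    """SSTF flag: |log2FC| >= log2(fc_threshold) and adjusted P <= alpha
    (both boundaries inclusive); direction from the fold-change sign."""
    log2fc = np.asarray(log2fc, dtype=float)
    adj_p = np.asarray(adj_p, dtype=float)
    sstf = (np.abs(log2fc) >= np.log2(fc_threshold)) & (adj_p <= alpha)
    direction = np.where(~sstf, "none", np.where(log2fc > 0, "up_in_A", "down_in_A"))
    return sstf, direction


def pairwise_de(
    cm: CountMatrix,
    contrast: tuple[str, str],
    phi: float | None = None,
    size_factors: pd.Series | None = None,
    fc_threshold: float = 2.0,
    alpha: float = 0.05,
    pseudocount: float = 0.5,
) -> PairwiseDE:
    """Full exact-test DE for one genotype contrast (A vs B).

    Size factors and the common dispersion are estimated across the whole
    matrix unless supplied.  Genes with all-zero counts in the contrast get
    p = 1 / log2FC = 0 and are excluded from the BH denominator.
    """
    a_samples = cm.samples_of(contrast[0])
    b_samples = cm.samples_of(contrast[1])
    if not a_samples or not b_samples:
        raise ValueError(f"missing samples for contrast {contrast}")
    if size_factors is None:
        size_factors = normalize(cm.counts)
    if phi is None:
        phi = estimate_common_dispersion(cm.counts, cm.genotype_of_sample, size_factors)
    sfa = size_factors[a_samples].to_numpy()
    sfb = size_factors[b_samples].to_numpy()
    ca = cm.counts[a_samples].to_numpy(dtype=float)
    cb = cm.counts[b_samples].to_numpy(dtype=float)
    norm_a = (ca / sfa).mean(axis=1)
    norm_b = (cb / sfb).mean(axis=1)
    log2fc = np.log2((norm_a + pseudocount) / (norm_b + pseudocount))
    nonzero = (ca.sum(axis=1) + cb.sum(axis=1)) > 0
    pvals = np.ones(len(cm.genes))
    for i in np.nonzero(nonzero)[0]:
        pvals[i] = nb_exact_test(ca[i], cb[i], phi, sfa, sfb)
    log2fc = np.where(nonzero, log2fc, 0.0)
    padj = np.ones(len(cm.genes))
    padj[nonzero] = bh_adjust(pvals[nonzero])
    sstf, direction = call_sstf(log2fc, padj, fc_threshold, alpha)
    table = pd.DataFrame(
        {
            "log2fc": log2fc,
            "pvalue": pvals,
            "padj": padj,
            "sstf": sstf,
            "direction": direction,
        },
        index=pd.Index(cm.genes, name="gene"),
    )
    return PairwiseDE(contrast, table)


def _set_direction(gene_dirs: list[str]) -> str:
    dirs = set(gene_dirs)
    if dirs == {"PIF-induced"}:
        return "PIF-induced"
    if dirs == {"PIF-repressed"}:
        return "PIF-repressed"
    return "ambiguous"


def build_composite_sets(results: dict[tuple[str, str], PairwiseDE]) -> CompositeSets:
    """Union the SSTF sets of each pair of defining contrasts.

    Composite sets: quartet-regulated = SSTF(pifq vs WT); PIF3-regulated =
    SSTF(pif3 vs WT) u SSTF(pifq vs pif145); PIF1/4/5-trio-regulated =
    SSTF(pif145 vs WT) u SSTF(pifq vs pif3).  A gene is PIF-induced when
    expression is lower in the more-mutant genotype in every SSTF-passing
    defining contrast (log2FC < 0 with the mutant first); conflicting
    contrasts make it ambiguous.
    """
    needed = set(STANDARD_CONTRASTS)
    if not needed <= set(results):
        raise ValueError(f"missing contrasts: {sorted(needed - set(results))}")
    universes = {tuple(r.table.index) for r in results.values()}
    if len(universes) != 1:
        raise ValueError("contrasts computed on different gene universes")

    def sstf_set(c):
        t = results[c].table
        return set(t.index[t["sstf"]])

    def gene_dir(c, g):
        fc = results[c].table.loc[g, "log2fc"]
        return "PIF-induced" if fc < 0 else "PIF-repressed"

    defs = {
        "quartet": [("pifq", "WT")],
        "pif3": [("pif3", "WT"), ("pifq", "pif145")],
        "trio145": [("pif145", "WT"), ("pifq", "pif3")],
    }
    sets = {}
    direction = {}
    for name, contrasts in defs.items():
        members = set().union(*(sstf_set(c) for c in contrasts))
        sets[name] = members
        direction[name] = {
            g: _set_direction([gene_dir(c, g) for c in contrasts if g in sstf_set(c)])
            for g in members
        }
    return CompositeSets(
        quartet_regulated=sets["quartet"],
        pif3_regulated=sets["pif3"],
        trio145_regulated=sets["trio145"],
        direction=direction,
    )
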