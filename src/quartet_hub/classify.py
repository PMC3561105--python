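"""W/X/Y/Z target classes and per-PIF contribution partitioning.

Bound genes (promoter-localized, motif-coincident binding sites) are
partitioned by membership in the PIF3-regulated and PIF-quartet-regulated
composite sets: W = bound only, X = bound + PIF3-regulated, Y = bound +
quartet-regulated, Z = bound + both.  Y-class genes with a moderate
(> 1.5-fold) but statistically supported PIF3 effect are promoted to YZ1.5.
The autonomous contribution of PIF i is the share of the total
quartet-dependent expression (WT minus pifq) recovered by the triple mutant
retaining only PIF i.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

from quartet_hub.de import CompositeSets

#: Triple mutant retaining only the given PIF.
TRIPLE_OF_PIF: dict[int, str] = {1: "pif345", 3: "pif145", 4: "pif135", 5: "pif134"}


@dataclass
class TargetClassification:
    gene_id: str
    bound: bool
    target_class: str  # W, X, Y, Z, unbound-regulated, none
    yz15: bool
    direction: str  # PIF-induced, PIF-repressed, ambiguous, none


def classify_targets(
    bound_gene_ids: set[str],
    sets: CompositeSets,
    universe: list[str] | None = None,
) -> list[TargetClassification]:
    """Assign each gene its W/X/Y/Z (or unbound-regulated / none) class.

    The four classes partition the bound genes; regulated-but-unbound genes
    are labeled separately.  Direction comes from the composite-set
    directions (conflicts -> ambiguous).
    """
    if universe is None:
        universe = sorted(bound_gene_ids | sets.quartet_regulated | sets.pif3_regulated)
    out = []
    for g in universe:
        bound = g in bound_gene_ids
        in_p3 = g in sets.pif3_regulated
        in_q = g in sets.quartet_regulated
        if bound:
            cls = {(False, False): "W", (True, False): "X", (False, True): "Y", (True, True): "Z"}[
                (in_p3, in_q)
            ]
        else:
            cls = "unbound-regulated" if (in_p3 or in_q) else "none"
        dirs = set()
        if in_p3:
            dirs.add(sets.direction["pif3"][g])
        if in_q:
            dirs.add(sets.direction["quartet"][g])
        if not dirs:
            direction = "none"
        elif len(dirs) == 1:
            direction = dirs.pop()
        else:
            direction = "ambiguous"
        out.append(TargetClassification(g, bound, cls, False, direction))
    return out


def flag_yz15(
    classifications: list[TargetClassification],
    norm_counts: pd.DataFrame,
    genotype_of_sample: dict[str, str],
    threshold: float = 1.5,
    alpha: float = 0.05,
    pseudocount: float = 0.5,
) -> list[TargetClassification]:
    """Promote Y-class genes with a moderate PIF3 effect to YZ1.5.

    A Y-class gene is flagged when its pif145/pifq normalized fold-change
    exceeds ``threshold`` (strict) in the PIF-induced direction and an
    unadjusted one-sided two-sample t-test on log-normalized replicate
    values supports the increase at P < ``alpha`` (mirroring an RT-qPCR
    confirmation of a PIF3-promoted expression increase).
    """
    s145 = [s for s in norm_counts.columns if genotype_of_sample[s] == "pif145"]
    sq = [s for s in norm_counts.columns if genotype_of_sample[s] == "pifq"]
    if not s145 or not sq:
        raise ValueError("pif145 and pifq samples required for YZ1.5 flagging")
    for tc in classifications:
        if tc.target_class != "Y" or tc.gene_id not in norm_counts.index:
            continue
        a = norm_counts.loc[tc.gene_id, s145].to_numpy(dtype=float)
        b = norm_counts.loc[tc.gene_id, sq].to_numpy(dtype=float)
        fold = (a.mean() + pseudocount) / (b.mean() + pseudocount)
        if fold <= threshold:
            continue
        t = stats.ttest_ind(
            np.log2(a + pseudocount), np.log2(b + pseudocount), alternative="greater"
        )
        if t.pvalue < alpha:
            tc.yz15 = True
    return classifications


def _denominator_flag(e_wt: float, e_q: float, rel_tol: float = 1e-6, abs_floor: float = 1.0) -> bool:
    return abs(e_wt - e_q) < rel_tol * abs(e_wt) or (abs(e_wt) < abs_floor and abs(e_q) < abs_floor)


def contribution_matrix(mean_expression: pd.DataFrame) -> pd.DataFrame:
    """Percent contribution of each PIF from triple-mutant expression.

    ``mean_expression`` is genes x genotypes (mean normalized expression).
    For PIF i with triple mutant m_i retaining only that factor::

        percent_i = 100 * (E(m_i) - E(pifq)) / (E(WT) - E(pifq))

    Columns appear only for triple mutants present.  Contributions may be
    negative or exceed 100 and are not clipped; genes with a vanishing
    denominator are flagged and their percents set to NaN.
    """
    for required in ("WT", "pifq"):
        if required not in mean_expression.columns:
            raise ValueError(f"genotype {required!r} missing")
    present = {i: m for i, m in TRIPLE_OF_PIF.items() if m in mean_expression.columns}
    if not present:
        raise ValueError("no triple mutant genotype present")
    e_wt = mean_expression["WT"].to_numpy(dtype=float)
    e_q = mean_expression["pifq"].to_numpy(dtype=float)
    flagged = np.array([_denominator_flag(w, q) for w, q in zip(e_wt, e_q)])
    denom = np.where(flagged, np.nan, e_wt - e_q)
    out = pd.DataFrame(index=mean_expression.index)
    for i, m in sorted(present.items()):
        out[f"PIF{i}"] = 100.0 * (mean_expression[m].to_numpy(dtype=float) - e_q) / denom
    out["denominator_flag"] = flagged
    return out


def share_decomposition(mean_expression: pd.DataFrame) -> pd.DataFrame:
    """PIF3 vs PIF1/4/5-trio shares of the quartet-dependent expression.

    pif3_share = 100 * (E(pif145) - E(pifq)) / (E(WT) - E(pifq)) and
    trio_share = 100 * (E(WT) - E(pif145)) / (E(WT) - E(pifq)); by
    construction the two sum to exactly 100 whenever defined.
    """
    for required in ("WT", "pif145", "pifq"):
        if required not in mean_expression.columns:
            raise ValueError(f"genotype {required!r} missing")
    e_wt = mean_expression["WT"].to_numpy(dtype=float)
    e_145 = mean_expression["pif145"].to_numpy(dtype=float)
    e_q = mean_expression["pifq"].to_numpy(dtype=float)
    flagged = np.array([_denominator_flag(w, q) for w, q in zip(e_wt, e_q)])
    denom = np.where(flagged, np.nan, e_wt - e_q)
    return pd.DataFrame(
        {
            "pif3_share": 100.0 * (e_145 - e_q) / denom,
            "trio_share": 100.0 * (e_wt - e_145) / denom,
            "denominator_flag": flagged,
        },
        index=mean_expression.index,
    )


TABLE1_COLUMNS = [
    "functional_category",
    "locus",
    "annotation",
    "fi_quartet",
    "fi_pif3_lof",
    "fi_pif145_gof",
    "fi_direct_pif3",
    "category",
    "rapid_light_repression",
    "reciprocal_regulation",
]


def load_direct_target_table() -> pd.DataFrame:
    """Load the packaged direct-target gene table (36 rows).

    Columns: locus, annotation, the four printed fold-induction ratios
    (WT/pifq, WT/pif3, pif145/pifq, pif3/pifq), the transcriptional-response
    category (Class Z or Class YZ1.5), the rapid-light-repression and
    reciprocal light/shade annotations, and the functional category.
    """
    ref = resources.files("quartet_hub").joinpath("data/table1.tsv")
    with resources.as_file(ref) as path:
        df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns) != TABLE1_COLUMNS:
        raise ValueError(f"unexpected table columns: {list(df.columns)}")
    for i, row in df.iterrows():
        if pd.isna(row["locus"]) or pd.isna(row["category"]):
            raise ValueError(f"malformed direct-target table at row {i + 2}")
    for col in ("fi_quartet", "fi_pif3_lof", "fi_pif145_gof", "fi_direct_pif3"):
        df[col] = df[col].astype(float)
    return df


def count_table1(table: pd.DataFrame, **predicates: object) -> int:
    """Count rows matching the conjunction of column == value predicates."""
    mask = pd.Series(True, index=table.index)
    for col, value in predicates.items():
        if col not in table.columns:
            raise KeyError(col)
        mask &= table[col] == value
    return int(mask.sum())
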