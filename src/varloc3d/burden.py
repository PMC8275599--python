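"""Per-protein-length variant burden and group comparisons.

Burden is the number of variants in a protein divided by its length in
residues (aa^-1), which puts short and very long proteins on a common scale.
Groups of proteins (e.g. DNA-damage-response vs other interactors) are
compared with either Welch's unequal-variance t-test or the Wilcoxon
rank-sum test; proteins above the cohort 75th percentile of burden are
flagged as accumulators.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .curation import ProteinRecord, VariantRecord


@dataclass(frozen=True)
class GroupComparison:
    group_a: str
    group_b: str
    test: str  # welch_t | wilcoxon
    statistic: float
    p_value: float


def per_length_burden(count: int, length: int) -> float:
    """Variants per residue: exact ratio count/length."""
    if length < 1:
        raise ValueError(f"protein length must be >= 1, got {length}")
    if count < 0:
        raise ValueError("count must be non-negative")
    return count / length


def wilcoxon_rank_sum(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test.

    For pooled n <= 14 the p-value is exact: the rank-sum distribution is
    enumerated over all assignments of pooled mid-ranks to group A (ties
    handled by mid-ranks).  Larger samples use the normal approximation with
    tie correction.  Returns (standardized statistic, p).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([a, b])
    n1, n2 = a.size, b.size
    n = n1 + n2
    ranks = stats.rankdata(pooled)
    w = float(ranks[:n1].sum())
    mean_w = n1 * (n + 1) / 2.0
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    tie_counts = np.unique(pooled, return_counts=True)[1]
    var_w = (n1 * n2 / 12.0) * (n + 1 - (tie_counts**3 - tie_counts).sum() / (n * (n - 1)))
    z = (w - mean_w) / math.sqrt(var_w)
    if n <= 14:
        # exact two-sided p by full enumeration of C(n, n1) rank assignments
        dev = abs(w - mean_w)
        hits = total = 0
        for idx in itertools.combinations(range(n), n1):
            ws = ranks[list(idx)].sum()
            total += 1
            if abs(ws - mean_w) >= dev - 1e-12:
                hits += 1
        return z, hits / total
    return z, 2.0 * stats.norm.sf(abs(z))


def compare_burden(burdens_a: Sequence[float], burdens_b: Sequence[float],
                   test: str = "welch_t",
                   label_a: str = "a", label_b: str = "b") -> GroupComparison:
    """Compare two burden distributions.

    ``welch_t`` is the unequal-variance two-sample t-test (two-sided);
    ``wilcoxon`` the rank-sum test.  Outliers are not trimmed — all
    observations enter the test.
    """
    a = np.asarray(burdens_a, dtype=float)
    b = np.asarray(burdens_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    if test == "welch_t":
        if a.size < 2 or b.size < 2:
            raise ValueError("welch_t requires >= 2 observations per group")
        res = stats.ttest_ind(a, b, equal_var=False)
        statistic, p = float(res.statistic), float(res.pvalue)
    elif test == "wilcoxon":
        statistic, p = wilcoxon_rank_sum(a, b)
    else:
        raise ValueError(f"unknown test {test!r}")
    return GroupComparison(label_a, label_b, test, statistic, min(p, 1.0))


def percentile_flag(burdens: Mapping[str, float], q: float = 0.75) -> set[str]:
    """Proteins whose burden strictly exceeds the q-th quantile of the cohort
    (linear-interpolation quantile)."""
    if not burdens:
        raise ValueError("burdens must be nonempty")
    if not 0.0 < q < 1.0:
        raise ValueError(f"q must lie in (0, 1), got {q}")
    threshold = float(np.quantile(np.asarray(list(burdens.values()), dtype=float), q))
    return {p for p, v in burdens.items() if v > threshold}


def burden_table(variants: Iterable[VariantRecord],
                 proteins: Mapping[str, ProteinRecord],
                 q: float = 0.75) -> pd.DataFrame:
    """Per-protein burden per analysis class, with 75th-percentile flags.

    Returns a tidy frame with columns protein, class, count, length, burden,
    flagged.  Flags are computed within each class across the cohort.
    """
    counts: dict[tuple[str, str], int] = {}
    for v in variants:
        if v.gene_symbol not in proteins:
            continue
        key = (v.gene_symbol, v.analysis_class)
        counts[key] = counts.get(key, 0) + 1
    rows = []
    classes = sorted({c for _, c in counts})
    for cls in classes:
        per_protein = {g: counts.get((g, cls), 0) / proteins[g].length
                       for g in proteins}
        flagged = percentile_flag(per_protein, q)
        for g, prot in proteins.items():
            cnt = counts.get((g, cls), 0)
            rows.append((g, cls, cnt, prot.length, cnt / prot.length, g in flagged))
    return pd.DataFrame(rows, columns=["protein", "class", "count", "length",
                                       "burden", "flagged"])


def pathway_burden(variants: Iterable[VariantRecord],
                   proteins: Mapping[str, ProteinRecord],
                   pathway_map: Mapping[str, Iterable[str]],
                   exclude_genes: Optional[Iterable[str]] = None) -> pd.DataFrame:
    """Variant counts aggregated per (pathway, analysis class).

    A variant contributes to every pathway its gene belongs to.  The frame
    carries columns pathway, class, count; ``df.attrs`` records
    ``total_variants`` (each variant once) and ``total_contributions`` (sum
    over the table), which differ when genes sit in several pathways.
    ``exclude_genes`` is a report-level flag for dropping a dominating gene
    from plots; excluded variants are still counted in the attrs totals.
    """
    excluded = set(exclude_genes or ())
    rows: dict[tuple[str, str], int] = {}
    total_variants = 0
    for v in variants:
        total_variants += 1
        if v.gene_symbol in excluded:
            continue
        for pw in pathway_map.get(v.gene_symbol, ()):
            key = (pw, v.analysis_class)
            rows[key] = rows.get(key, 0) + 1
    df = pd.DataFrame([(pw, cls, n) for (pw, cls), n in rows.items()],
                      columns=["pathway", "class", "count"])
    df = df.sort_values(["pathway", "class"], ignore_index=True)
    df.attrs["total_variants"] = total_variants
    df.attrs["total_contributions"] = int(df["count"].sum()) if len(df) else 0
    return df


def read_pathway_map(path) -> dict[str, set[str]]:
    """Read a gene→pathway TSV (columns gene, pathway) into a mapping."""
    df = pd.read_csv(path, sep="\t", comment="#")
    out: dict[str, set[str]] = {}
    for r in df.itertuples(index=False):
        out.setdefault(str(r.gene), set()).add(str(r.pathway))
    return out
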