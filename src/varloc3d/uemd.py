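"""Rank-based unidirectional earth mover's distance (uEMD) for
tumor-vs-background differential mutation scoring.

Following the DiffMut approach, each individual's per-gene mutation counts
are converted to normalized ranks in [0, 1] (mean ranks for ties, divided by
the number of genes), so every individual contributes the same total rank
mass regardless of mutation load.  Per gene, the ranks across a cohort's
individuals are binned into a histogram on [0, 1]; the uEMD between a
tumor and a background histogram is the transport cost of moving the tumor's
*excess* upper-tail mass downward:

    uEMD = sum_k max(0, C_k) / n_bins,   C_k = sum_{j >= k} (t_j - g_j)

with bins indexed low -> high rank.  Only excess tumor mass at the top
counts, so a gene whose background variation dominates its somatic mutation
profile scores exactly 0.  Significance comes from permuting cohort labels
of individuals, with Benjamini-Hochberg q-values.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .burden import wilcoxon_rank_sum


@dataclass(frozen=True)
class CohortMatrix:
    """Individuals x genes non-negative mutation-count matrix."""

    cohort_label: str
    kind: str  # tumor | background
    counts: pd.DataFrame  # index: individuals, columns: genes

    def __post_init__(self) -> None:
        if self.kind not in ("tumor", "background"):
            raise ValueError(f"kind must be tumor|background, got {self.kind!r}")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def genes(self) -> list[str]:
        return list(self.counts.columns)


@dataclass(frozen=True)
class DiffScore:
    gene: str
    uEMD: float
    q_value: Optional[float] = None


def rank_normalize(counts: Sequence[float]) -> np.ndarray:
    """Normalized ranks of one individual's counts across genes.

    Genes are ranked ascending by count, ties get the mean rank, and ranks
    are divided by the number of genes, giving values in (0, 1].
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 1 or counts.size == 0:
        raise ValueError("counts must be a nonempty 1-D array")
    return stats.rankdata(counts) / counts.size


def rank_normalize_matrix(counts: pd.DataFrame) -> np.ndarray:
    """Row-wise rank normalization of an individuals x genes matrix."""
    return stats.rankdata(counts.to_numpy(), axis=1) / counts.shape[1]


def build_histogram(normalized_ranks: Sequence[float], n_bins: int = 100) -> np.ndarray:
    """Histogram of one gene's normalized ranks across individuals.

    Equal-width bins on [0, 1], last bin right-closed; masses sum to 1.
    """
    ranks = np.asarray(normalized_ranks, dtype=float)
    if ranks.size == 0:
        raise ValueError("at least one individual required")
    counts, _ = np.histogram(ranks, bins=np.linspace(0.0, 1.0, n_bins + 1))
    return counts / ranks.size


def uemd(tumor_hist: np.ndarray, background_hist: np.ndarray) -> float:
    """Unidirectional EMD between two unit-mass rank histograms.

    With C_k the cumulative (tumor - background) mass from the top bin down
    to bin k, uEMD = sum_k max(0, C_k) / n_bins.  Zero when tumor mass never
    exceeds background in any upper tail.
    """
    t = np.asarray(tumor_hist, dtype=float)
    g = np.asarray(background_hist, dtype=float)
    if t.shape != g.shape:
        raise ValueError("histograms must have the same number of bins")
    c = np.cumsum((t - g)[::-1])  # c[i] = sum over the top i+1 bins
    c[np.abs(c) < 1e-12] = 0.0  # cancellations must give an exact zero score
    return float(np.clip(c, 0.0, None).sum() / t.size)


def uemd_scores(tumor: CohortMatrix, background: CohortMatrix,
                n_bins: int = 100) -> pd.Series:
    """Per-gene uEMD scores for a tumor cohort against a background cohort."""
    genes = tumor.genes
    if genes != background.genes:
        raise ValueError("cohorts must share an identical gene set")
    rt = rank_normalize_matrix(tumor.counts)
    rg = rank_normalize_matrix(background.counts)
    return pd.Series(_scores_from_ranks(rt, rg, n_bins), index=genes, name="uEMD")


def _scores_from_ranks(rt: np.ndarray, rg: np.ndarray, n_bins: int) -> np.ndarray:
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    out = np.empty(rt.shape[1])
    for j in range(rt.shape[1]):
        th, _ = np.histogram(rt[:, j], bins=edges)
        gh, _ = np.histogram(rg[:, j], bins=edges)
        out[j] = uemd(th / rt.shape[0], gh / rg.shape[0])
    return out


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """BH step-up adjusted p-values (q-values), monotone nondecreasing in p."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.clip(q_sorted, 0.0, 1.0)
    return q


def uemd_qvalues(tumor: CohortMatrix, background: CohortMatrix,
                 n_bins: int = 100, n_perm: int = 200,
                 seed: int = 0) -> pd.DataFrame:
    """uEMD scores with permutation p-values and BH q-values.

    The null permutes cohort labels of individuals (pooling both cohorts and
    redrawing tumor/background assignments of the original sizes), recomputes
    per-gene scores, and estimates each gene's p as
    (1 + #{null >= observed}) / (n_perm + 1) against its own null scores.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    genes = tumor.genes
    observed = uemd_scores(tumor, background, n_bins).to_numpy()
    pooled = np.vstack([tumor.counts.to_numpy(), background.counts.to_numpy()])
    pooled_ranks = stats.rankdata(pooled, axis=1) / pooled.shape[1]
    n_t = tumor.counts.shape[0]
    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(genes))
    for _ in range(n_perm):
        perm = rng.permutation(pooled.shape[0])
        null = _scores_from_ranks(pooled_ranks[perm[:n_t]],
                                  pooled_ranks[perm[n_t:]], n_bins)
        exceed += null >= observed
    p = (exceed + 1) / (n_perm + 1)
    return pd.DataFrame({"gene": genes, "uEMD": observed, "p_value": p,
                         "q_value": benjamini_hochberg(p)})


def compare_gene_sets(scores: Mapping[str, float], set_a: Iterable[str],
                      set_b: Iterable[str]) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum comparison of uEMD scores between two gene
    sets (e.g. DNA-damage-response vs other genes).  Returns (statistic, p)."""
    a = [scores[g] for g in set_a]
    b = [scores[g] for g in set_b]
    if not a or not b:
        raise ValueError("both gene sets must be nonempty")
    return wilcoxon_rank_sum(a, b)


def read_cohort_matrix(path, cohort_label: str, kind: str) -> CohortMatrix:
    """Read an individuals x genes count matrix TSV (first column: individual
    id) into a CohortMatrix."""
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    return CohortMatrix(cohort_label, kind, df.astype(int))


def maf_to_matrix(path, cohort_label: str, kind: str,
                  genes: Optional[Sequence[str]] = None) -> CohortMatrix:
    """Aggregate a MAF-like TSV (columns sample, gene) to a count matrix."""
    df = pd.read_csv(path, sep="\t", comment="#")
    mat = pd.crosstab(df["sample"], df["gene"])
    if genes is not None:
        mat = mat.reindex(columns=list(genes), fill_value=0)
    return CohortMatrix(cohort_label, kind, mat)
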