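"""Class-wise localization fractions and sequence-position distributions.

Two questions are addressed here.  First, what fraction of each variant
class (pathogenic / benign / VUS germline; primary / metastatic somatic)
falls in Pfam domains or interaction interfaces, and are the fractions of
two classes different — tested with the "N-1" chi-squared test on the 2x2
table, Bonferroni/Dunn-adjusted over the pairwise comparisons.  Second, do
two classes distribute differently along the protein sequence — summarized
by fixed-width position histograms (default 75-residue bins), boundary-
reflected Gaussian kernel densities, and the two-sample Kolmogorov-Smirnov
D statistic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .features import AnnotatedVariant


@dataclass(frozen=True)
class KSResult:
    D: float
    p_value: float


@dataclass(frozen=True)
class PositionDistribution:
    """Positions of one variant class on one protein, with histogram and
    smoothed density."""

    protein_id: str
    class_label: str
    positions: tuple[int, ...]
    bin_width: int
    bin_edges: tuple[int, ...]  # right-exclusive residue edges
    histogram: tuple[int, ...]
    grid: Optional[np.ndarray] = None
    density: Optional[np.ndarray] = None


def fraction_in_feature(annotated: Sequence[AnnotatedVariant], kind: str) -> float:
    """Percentage of a class's variants falling in a feature kind.

    Returns NaN for an empty class (undefined, reported as NA).
    """
    n_total = len(annotated)
    if n_total == 0:
        return float("nan")
    attr = {"pfam_domain": "in_domain", "interface": "in_interface", "idr": "in_idr"}[kind]
    n_in = sum(1 for av in annotated if getattr(av, attr))
    return 100.0 * n_in / n_total


def n1_chisq(x1: int, n1: int, x2: int, n2: int) -> tuple[float, float]:
    """"N-1" chi-squared test for two independent proportions.

    The Pearson chi-squared statistic of the 2x2 table is scaled by
    (N-1)/N with N = n1 + n2; the two-sided p comes from chi-squared with
    1 df.  Degenerate tables (an all-zero margin) give statistic 0, p 1.
    """
    if n1 < 1 or n2 < 1:
        raise ValueError("n1 and n2 must be >= 1")
    if not (0 <= x1 <= n1 and 0 <= x2 <= n2):
        raise ValueError("x must lie in [0, n]")
    N = n1 + n2
    a, b = x1, n1 - x1
    c, d = x2, n2 - x2
    margins = [(a + b), (c + d), (a + c), (b + d)]
    if any(m == 0 for m in margins):
        return 0.0, 1.0
    pearson = N * (a * d - b * c) ** 2 / (margins[0] * margins[1] * margins[2] * margins[3])
    statistic = pearson * (N - 1) / N
    return float(statistic), float(stats.chi2.sf(statistic, df=1))


def dunn_adjust(p_values: Sequence[float], m: Optional[int] = None) -> list[float]:
    """Dunn (Bonferroni-type) adjustment: p_adj = min(1, p * m).

    ``m`` defaults to the number of comparisons supplied.
    """
    p_values = list(p_values)
    if m is None:
        m = len(p_values)
    if m < 1:
        raise ValueError("m must be >= 1")
    return [min(1.0, p * m) for p in p_values]


def localization_tests(annotated_by_class: dict[str, Sequence[AnnotatedVariant]],
                       kinds: Sequence[str] = ("pfam_domain", "interface")) -> pd.DataFrame:
    """All pairwise class comparisons of feature fractions.

    For each feature kind and each unordered class pair, runs the "N-1"
    chi-squared test on in-feature counts; p-values are Dunn-adjusted over
    the pairwise comparisons within each kind.  Returns a tidy frame with
    columns kind, class_a, class_b, pct_a, pct_b, statistic, p_raw, p_adj.
    """
    attr = {"pfam_domain": "in_domain", "interface": "in_interface", "idr": "in_idr"}
    classes = [c for c, avs in annotated_by_class.items() if len(avs)]
    rows = []
    for kind in kinds:
        pairs = [(classes[i], classes[j])
                 for i in range(len(classes)) for j in range(i + 1, len(classes))]
        raw = []
        for ca, cb in pairs:
            xa = sum(1 for av in annotated_by_class[ca] if getattr(av, attr[kind]))
            xb = sum(1 for av in annotated_by_class[cb] if getattr(av, attr[kind]))
            na, nb = len(annotated_by_class[ca]), len(annotated_by_class[cb])
            statistic, p = n1_chisq(xa, na, xb, nb)
            raw.append((ca, cb, 100 * xa / na, 100 * xb / nb, statistic, p))
        adj = dunn_adjust([r[5] for r in raw], m=len(pairs)) if pairs else []
        for (ca, cb, pa, pb, s, p), pa_adj in zip(raw, adj):
            rows.append((kind, ca, cb, pa, pb, s, p, pa_adj))
    return pd.DataFrame(rows, columns=["kind", "class_a", "class_b", "pct_a",
                                       "pct_b", "statistic", "p_raw", "p_adj"])


def position_histogram(positions: Sequence[int], length: int,
                       bin_width: int = 75) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of residue positions in fixed-width sequence bins.

    Bins are [1-75], [76-150], ... with the last bin truncated at the
    protein length.  Returns (counts, edges) where ``edges`` are the
    right-exclusive residue boundaries (edges[i] <= pos < edges[i+1]).
    """
    if length < 1 or bin_width < 1:
        raise ValueError("length and bin_width must be >= 1")
    positions = np.asarray(positions, dtype=int)
    if positions.size and (positions.min() < 1 or positions.max() > length):
        raise ValueError("positions must lie within [1, length]")
    edges = np.arange(1, length + 1, bin_width)
    edges = np.append(edges, length + 1)
    counts, _ = np.histogram(positions, bins=edges)
    return counts, edges


def ks_two_sample(positions_a: Sequence[float], positions_b: Sequence[float]) -> KSResult:
    """Two-sample Kolmogorov-Smirnov comparison of position distributions.

    D is the maximum absolute difference between the two empirical CDFs;
    p comes from the exact small-sample distribution where feasible and the
    asymptotic Kolmogorov distribution otherwise.
    """
    a = np.asarray(positions_a, dtype=float)
    b = np.asarray(positions_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    res = stats.ks_2samp(a, b, method="auto")
    return KSResult(float(res.statistic), float(min(res.pvalue, 1.0)))


def density_curve(positions: Sequence[float], length: int,
                  bandwidth: str | float = "silverman",
                  grid_step: float = 1.0) -> Optional[tuple[np.ndarray, np.ndarray]]:
    """Gaussian kernel density of variant positions on the residue grid.

    The kernel is reflected at the sequence boundaries [1, length] so no
    mass leaks outside the protein, and the curve is renormalized to unit
    mass on the grid.  Returns (grid, density), or None for fewer than two
    positions (NA curve).
    """
    x = np.asarray(positions, dtype=float)
    if x.size < 2:
        return None
    lo, hi = 1.0, float(length)
    grid = np.arange(lo, hi + grid_step / 2, grid_step)
    if np.ptp(x) == 0.0:
        h = 1.0  # degenerate sample: unit-residue kernel at the common position
        dens = _reflected_gauss(grid, x, h, lo, hi)
    else:
        if bandwidth == "silverman":
            sd = x.std(ddof=1)
            iqr = np.subtract(*np.percentile(x, [75, 25]))
            sigma = min(sd, iqr / 1.349) if iqr > 0 else sd
            h = 0.9 * sigma * x.size ** (-1 / 5)
        else:
            h = float(bandwidth)
        dens = _reflected_gauss(grid, x, h, lo, hi)
    mass = np.trapezoid(dens, grid)
    return grid, dens / mass


def _reflected_gauss(grid: np.ndarray, x: np.ndarray, h: float,
                     lo: float, hi: float) -> np.ndarray:
    def kde(points):
        z = (grid[:, None] - points[None, :]) / h
        return np.exp(-0.5 * z**2).sum(axis=1) / (x.size * h * math.sqrt(2 * math.pi))

    return kde(x) + kde(2 * lo - x) + kde(2 * hi - x)


def position_distribution(protein_id: str, class_label: str,
                          positions: Sequence[int], length: int,
                          bin_width: int = 75) -> PositionDistribution:
    """Bundle histogram + density for one class on one protein."""
    counts, edges = position_histogram(positions, length, bin_width)
    curve = density_curve(positions, length)
    grid, dens = curve if curve is not None else (None, None)
    return PositionDistribution(
        protein_id=protein_id, class_label=class_label,
        positions=tuple(int(p) for p in positions), bin_width=bin_width,
        bin_edges=tuple(int(e) for e in edges), histogram=tuple(int(c) for c in counts),
        grid=grid, density=dens)


def compare_position_distributions(dist_a: Iterable[int], dist_b: Iterable[int]
                                   ) -> KSResult:
    """Convenience wrapper: KS comparison of two position samples."""
    return ks_two_sample(list(dist_a), list(dist_b))
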