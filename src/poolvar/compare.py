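"""Pairwise comparison of zero-inflated VAF distributions.

Most entries of a pool-VAF vector are exactly zero (the accession does not
carry the variant), so a plain rank-sum test wastes power and miscalibrates.
The two-part Wilcoxon test (Lachenbruch) splits each comparison into

* B: a pooled-variance two-proportion z-statistic on the fraction of zeros,
* W: a tie-corrected normal-approximation Wilcoxon rank-sum z-statistic on
  the nonzero values,

and refers X^2 = B^2 + W^2 to chi-square with 2 df.  When only one part is
computable (no zeros anywhere, or no nonzero data) the available part alone
is referred to chi-square with 1 df; when neither part is computable the
samples are indistinguishable and p = 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

__all__ = [
    "TwoPartResult",
    "two_part_wilcoxon",
    "pairwise_significance",
    "cluster_significance_matrix",
    "export_distribution_summaries",
]


@dataclass(frozen=True)
class TwoPartResult:
    statistic: float        # X^2
    df: int                 # 2, 1, or 0 (fully degenerate)
    pvalue: float
    reject: bool
    b_stat: float           # proportion-of-zeros z (nan when degenerate)
    w_stat: float           # rank-sum z on nonzero values (nan when degenerate)
    degenerate: bool        # True when no part was computable


def _proportion_z(n_zero_x: int, n_x: int, n_zero_y: int, n_y: int) -> float:
    """Pooled two-proportion z; nan when the pooled proportion is 0 or 1."""
    p_pool = (n_zero_x + n_zero_y) / (n_x + n_y)
    if p_pool in (0.0, 1.0):
        return np.nan
    se = np.sqrt(p_pool * (1 - p_pool) * (1 / n_x + 1 / n_y))
    return (n_zero_x / n_x - n_zero_y / n_y) / se


def _ranksum_z(x: np.ndarray, y: np.ndarray) -> float:
    """Tie-corrected normal-standardized Wilcoxon rank-sum z on x vs y.

    nan when either sample is empty or all pooled values tie.
    """
    m, n = len(x), len(y)
    if m == 0 or n == 0:
        return np.nan
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    w = ranks[:m].sum()
    mu = m * (m + n + 1) / 2.0
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = (counts**3 - counts).sum()
    var = m * n / 12.0 * ((m + n + 1) - tie_term / ((m + n) * (m + n - 1)))
    if var <= 0:
        return np.nan
    return (w - mu) / np.sqrt(var)


def two_part_wilcoxon(x: Sequence[float], y: Sequence[float],
                      alpha: float = 0.05) -> TwoPartResult:
    """Two-part Wilcoxon comparison of two zero-inflated samples."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    b = _proportion_z(int((x == 0).sum()), x.size, int((y == 0).sum()), y.size)
    w = _ranksum_z(x[x > 0], y[y > 0])
    parts = [z for z in (b, w) if np.isfinite(z)]
    if not parts:
        return TwoPartResult(0.0, 0, 1.0, False, b, w, True)
    x2 = float(np.sum(np.square(parts)))
    df = len(parts)
    p = float(stats.chi2.sf(x2, df))
    return TwoPartResult(x2, df, p, p < alpha, b, w, False)


def pairwise_significance(vectors: Mapping[str, Sequence[float]] | pd.DataFrame,
                          alpha: float = 0.05,
                          bonferroni: bool = False) -> pd.DataFrame:
    """Binary accession x accession matrix: 1 where VAF distributions differ.

    Every unordered pair is tested at ``alpha`` with no multiplicity
    correction by default (a Bonferroni option divides alpha by the number
    of pairs).  The result is symmetric with zero diagonal.
    """
    if isinstance(vectors, pd.DataFrame):
        vectors = {c: vectors[c].to_numpy() for c in vectors.columns}
    names = list(vectors)
    if len(names) < 2:
        raise ValueError("need at least two accessions")
    k = len(names) * (len(names) - 1) // 2
    level = alpha / k if bonferroni else alpha
    mat = pd.DataFrame(0, index=names, columns=names, dtype=int)
    for i, a in enumerate(names):
        for b_name in names[i + 1:]:
            res = two_part_wilcoxon(vectors[a], vectors[b_name], alpha=level)
            mat.loc[a, b_name] = mat.loc[b_name, a] = int(res.reject)
    return mat


def cluster_significance_matrix(matrix: pd.DataFrame
                                ) -> tuple[np.ndarray, pd.Series]:
    """Complete-linkage clustering of the binary significance matrix.

    The matrix itself is the dissimilarity (0 = indistinguishable, 1 =
    different).  Flat clusters cut just below 1, so accessions merge exactly
    when their complete-linkage height is 0 — i.e. groups of mutually
    non-different accessions.

    Returns (scipy linkage matrix, accession -> cluster id Series).
    """
    m = matrix.to_numpy(dtype=float)
    if m.shape[0] != m.shape[1] or not np.array_equal(m, m.T) or np.diag(m).any():
        raise ValueError("need a symmetric binary matrix with zero diagonal")
    condensed = squareform(m, checks=False)
    link = hierarchy.linkage(condensed, method="complete")
    flat = hierarchy.fcluster(link, t=0.5, criterion="distance")
    return link, pd.Series(flat, index=matrix.index, name="cluster")


def export_distribution_summaries(vectors: Mapping[str, Sequence[float]] | pd.DataFrame,
                                  grid_size: int = 64) -> pd.DataFrame:
    """Per-accession summaries backing strip/violin plots.

    Median, mean, fraction of zeros, heterozygote-band fraction (VAF in
    [0.3, 0.5], the signature of hybrid material), near-fixed fraction
    (>= 0.7), plus a Gaussian-KDE density evaluated on a [0, 1] grid
    (flat-zero when the vector is degenerate).
    """
    if isinstance(vectors, pd.DataFrame):
        vectors = {c: vectors[c].to_numpy() for c in vectors.columns}
    grid = np.linspace(0.0, 1.0, grid_size)
    rows = []
    for name, v in vectors.items():
        v = np.asarray(v, dtype=float)
        if np.ptp(v) > 0:
            density = stats.gaussian_kde(v)(grid)
        else:
            density = np.zeros_like(grid)
        rows.append({
            "accession": name,
            "median": float(np.median(v)),
            "mean": float(v.mean()),
            "frac_zero": float((v == 0).mean()),
            "frac_het_band": float(((v >= 0.3) & (v <= 0.5)).mean()),
            "frac_high": float((v >= 0.7).mean()),
            "density": density,
        })
    return pd.DataFrame(rows).set_index("accession")
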