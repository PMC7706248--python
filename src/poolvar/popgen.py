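"""VAF-based population genetics: Nei distance, NJ trees, PCoA, private alleles.

Pool VAFs are treated as population allele frequencies at biallelic loci
(alt frequency p, reference frequency q = 1 - p).  Nei's (1972) standard
genetic distance between accessions X and Y is

    D = -ln( Jxy / sqrt(Jx * Jy) )

with Jx = mean_l(p_X^2 + q_X^2), Jy likewise, and
Jxy = mean_l(p_X p_Y + q_X q_Y).  The distance matrix feeds a
Studier-Keppler Neighbor-Joining tree and a classical PCoA
(Gower double-centering + eigendecomposition).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import TreeNode

__all__ = [
    "nei_distance",
    "cap_infinite",
    "neighbor_joining",
    "Ordination",
    "pcoa",
    "private_allele_stats",
]


def nei_distance(freqs: pd.DataFrame) -> pd.DataFrame:
    """Nei's (1972) genetic distance from an accessions x loci frequency matrix.

    Rows are accessions, columns loci, entries the alt-allele frequency in
    [0, 1].  Pairs with zero inter-population gene identity (Jxy = 0) get
    ``inf``; :func:`cap_infinite` maps those to a large finite value before
    tree building.
    """
    p = freqs.to_numpy(dtype=float)
    if p.ndim != 2 or p.shape[0] < 2 or p.shape[1] < 1:
        raise ValueError("need at least 2 accessions and 1 locus")
    if np.isnan(p).any() or p.min() < 0 or p.max() > 1:
        raise ValueError("frequencies must be in [0, 1] with no missing entries")
    q = 1.0 - p
    # per-accession homozygosity J_x and cross-products J_xy, averaged over loci
    jx = (p**2 + q**2).mean(axis=1)
    jxy = (p @ p.T + q @ q.T) / p.shape[1]
    ratio = np.divide(jxy, np.sqrt(np.outer(jx, jx)),
                      out=np.zeros_like(jxy), where=jxy > 0)
    with np.errstate(divide="ignore"):
        d = -np.log(ratio)      # zero gene identity -> infinite distance
    np.fill_diagonal(d, 0.0)
    d = np.maximum(d, 0.0)          # guard tiny negative rounding
    d = (d + d.T) / 2.0
    labels = list(freqs.index)
    return pd.DataFrame(d, index=labels, columns=labels)


def cap_infinite(dist: pd.DataFrame, factor: float = 10.0) -> pd.DataFrame:
    """Replace infinite distances by factor x the largest finite entry."""
    d = dist.to_numpy(dtype=float).copy()
    finite = np.isfinite(d)
    if finite.all():
        return dist.copy()
    cap = d[finite].max() * factor if finite.any() else factor
    d[~finite] = cap
    return pd.DataFrame(d, index=dist.index, columns=dist.columns)


def neighbor_joining(dist: pd.DataFrame, *, clamp_negative: bool = False) -> TreeNode:
    """Neighbor-Joining (Saitou-Nei) with the Studier-Keppler Q criterion.

    Returns an unrooted tree as a trifurcating-rooted :class:`skbio.TreeNode`
    (the standard Newick representation of an unrooted binary tree).  Ties in
    Q-minimization break to the lowest index pair so trees are reproducible.
    Negative branch lengths are kept unless ``clamp_negative``.
    """
    labels = [str(x) for x in dist.index]
    d = dist.to_numpy(dtype=float).copy()
    if not np.isfinite(d).all():
        raise ValueError("infinite distances: apply cap_infinite() first")
    if d.shape[0] != d.shape[1] or not np.allclose(d, d.T) or np.diag(d).any():
        raise ValueError("need a symmetric matrix with zero diagonal")
    n = len(labels)
    if n < 2:
        raise ValueError("need at least 2 taxa")
    nodes = [TreeNode(name=lbl) for lbl in labels]
    if n == 2:
        root = TreeNode()
        nodes[0].length = d[0, 1]
        nodes[1].length = 0.0
        root.extend(nodes)
        return root

    def _edge(length: float) -> float:
        return max(length, 0.0) if clamp_negative else length

    active = list(range(n))
    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # lowest-index pair among the minima (row-major argmin is exactly that)
        i, j = divmod(int(np.argmin(q)), m)
        if i > j:
            i, j = j, i
        ai, aj = active[i], active[j]
        dij = sub[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = dij - li
        parent = TreeNode()
        nodes[ai].length = _edge(li)
        nodes[aj].length = _edge(lj)
        parent.extend([nodes[ai], nodes[aj]])
        # distances from the new node u: d(u,k) = (d(i,k)+d(j,k)-d(i,j))/2
        new_row = 0.5 * (d[ai, :] + d[aj, :] - dij)
        d[ai, :] = new_row
        d[:, ai] = new_row
        d[ai, ai] = 0.0
        nodes[ai] = parent
        active.pop(j)
    # resolve the final three nodes around a trifurcating root
    a, b, c = active
    root = TreeNode()
    nodes[a].length = _edge(0.5 * (d[a, b] + d[a, c] - d[b, c]))
    nodes[b].length = _edge(0.5 * (d[a, b] + d[b, c] - d[a, c]))
    nodes[c].length = _edge(0.5 * (d[a, c] + d[b, c] - d[a, b]))
    root.extend([nodes[a], nodes[b], nodes[c]])
    return root


@dataclass
class Ordination:
    """PCoA result: eigenvalues (descending) and coordinates on positive axes."""

    eigenvalues: np.ndarray
    coordinates: pd.DataFrame      # accessions x retained axes
    proportion_explained: np.ndarray

    @property
    def n_axes(self) -> int:
        return self.coordinates.shape[1]


def pcoa(dist: pd.DataFrame) -> Ordination:
    """Classical principal coordinates analysis of a distance matrix.

    Gower-centers B = -1/2 * J D^2 J, eigendecomposes, and keeps coordinates
    only for numerically positive eigenvalues (eigenvector * sqrt(eigenvalue)).
    Negative eigenvalues (non-Euclidean input) are reported but carry no
    coordinates.
    """
    d = dist.to_numpy(dtype=float)
    if not np.isfinite(d).all():
        raise ValueError("distance matrix must be finite")
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    vals, vecs = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    tol = max(abs(vals[0]), 1.0) * 1e-10
    pos = vals > tol
    coords = vecs[:, pos] * np.sqrt(vals[pos])
    denom = vals[vals > 0].sum() or 1.0
    return Ordination(
        eigenvalues=vals,
        coordinates=pd.DataFrame(
            coords, index=dist.index,
            columns=[f"PCo{k + 1}" for k in range(coords.shape[1])],
        ),
        proportion_explained=np.where(vals > 0, vals / denom, 0.0),
    )


def private_allele_stats(summary: pd.DataFrame, vaf: pd.DataFrame,
                         metadata: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Private-allele counts per accession and VAF summaries per germplasm group.

    ``summary`` is the per-variant table from :func:`~poolvar.variants.summarize_variants`
    (aligned row-wise with ``vaf``), ``vaf`` the variants x accessions matrix,
    ``metadata`` an accession-indexed frame with a ``group`` column.

    Returns (per-accession frame: group, n_private, mean/median private VAF;
    per-group frame: mean count and mean/median VAF of private alleles).
    """
    unknown = set(vaf.columns) - set(metadata.index)
    if unknown:
        raise ValueError(f"accessions missing from metadata: {sorted(unknown)}")
    v = vaf.to_numpy(dtype=float)
    private = summary["private"].to_numpy(dtype=bool)
    rows = []
    for j, acc in enumerate(vaf.columns):
        mine = private & (v[:, j] > 0)
        vals = v[mine, j]
        rows.append({
            "accession": acc,
            "group": metadata.loc[acc, "group"],
            "n_private": int(mine.sum()),
            "mean_private_vaf": float(vals.mean()) if vals.size else np.nan,
            "median_private_vaf": float(np.median(vals)) if vals.size else np.nan,
        })
    per_acc = pd.DataFrame(rows).set_index("accession")
    group_rows = []
    for g, sub in per_acc.groupby("group", sort=False):
        pooled = np.concatenate([
            v[private & (v[:, j] > 0), j]
            for j, acc in enumerate(vaf.columns)
            if metadata.loc[acc, "group"] == g
        ]) if len(sub) else np.array([])
        group_rows.append({
            "group": g,
            "n_accessions": len(sub),
            "mean_private_per_accession": float(sub["n_private"].mean()),
            "mean_private_vaf": float(pooled.mean()) if pooled.size else np.nan,
            "median_private_vaf": float(np.median(pooled)) if pooled.size else np.nan,
        })
    per_group = pd.DataFrame(group_rows).set_index("group")
    return per_acc, per_group
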