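"""VAF-to-genotype-score conversion and threshold-sensitivity analysis.

Treating each pooled accession as if it were a single individual: VAF below
a lower bound scores 0 (reference homozygote), VAF at or above an upper
bound scores 1 (variant homozygote), anything in between scores 2
(heterozygote).  Three preset threshold pairs — (0.3, 0.7), (0.4, 0.6),
(0.2, 0.8) — probe how sensitive the resulting Euclidean-distance NJ
clustering is to the heterozygote band.  A VAF exactly at the lower bound
maps to 2 so the mapping is total on [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio import TreeNode

from .popgen import neighbor_joining

__all__ = [
    "ThresholdSetting",
    "PRESETS",
    "vaf_to_genotype",
    "genotype_matrix",
    "euclidean_distance",
    "threshold_sensitivity",
]


@dataclass(frozen=True)
class ThresholdSetting:
    lower: float
    upper: float

    def __post_init__(self) -> None:
        if not 0 < self.lower < self.upper <= 1:
            raise ValueError("need 0 < lower < upper <= 1")

    @property
    def name(self) -> str:
        return f"{self.lower:g}-{self.upper:g}"


PRESETS = (
    ThresholdSetting(0.3, 0.7),
    ThresholdSetting(0.4, 0.6),
    ThresholdSetting(0.2, 0.8),
)


def vaf_to_genotype(vaf: float | np.ndarray, setting: ThresholdSetting
                    ) -> int | np.ndarray:
    """Score a VAF (or array of VAFs): 0 below lower, 1 at/above upper, else 2."""
    v = np.asarray(vaf, dtype=float)
    if (v < 0).any() or (v > 1).any():
        raise ValueError("VAF out of [0, 1]")
    score = np.where(v < setting.lower, 0, np.where(v >= setting.upper, 1, 2))
    return int(score) if np.isscalar(vaf) or np.ndim(vaf) == 0 else score


def genotype_matrix(vafs: pd.DataFrame, setting: ThresholdSetting) -> pd.DataFrame:
    """Convert a variants x accessions VAF matrix to 0/1/2 scores."""
    return pd.DataFrame(vaf_to_genotype(vafs.to_numpy(), setting),
                        index=vafs.index, columns=vafs.columns, dtype=int)


def euclidean_distance(genos: pd.DataFrame) -> pd.DataFrame:
    """Pairwise plain Euclidean distance between accession score vectors.

    ``genos`` is variants x accessions (columns are compared).
    """
    m = genos.to_numpy(dtype=float).T
    d = squareform(pdist(m, metric="euclidean"))
    labels = list(genos.columns)
    return pd.DataFrame(d, index=labels, columns=labels)


def threshold_sensitivity(vafs: pd.DataFrame,
                          settings: tuple[ThresholdSetting, ...] = PRESETS
                          ) -> tuple[dict[str, TreeNode], pd.DataFrame]:
    """One NJ tree per threshold setting plus pairwise topology differences.

    Topology difference is the Robinson-Foulds distance between the unrooted
    trees; identical clusterings give 0.
    """
    trees = {
        s.name: neighbor_joining(euclidean_distance(genotype_matrix(vafs, s)))
        for s in settings
    }
    rows = []
    for a, b in combinations(trees, 2):
        rows.append({"setting_a": a, "setting_b": b,
                     "rf_distance": float(trees[a].compare_rfd(trees[b]))})
    return trees, pd.DataFrame(rows)
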