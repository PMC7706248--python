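"""Pool-level variant calls and allele-frequency tables.

Within one pooled accession sample the variant allele frequency (VAF) is the
fraction of alternate-allele reads; with 96 diploid plants per pool it
estimates the population allele frequency on 192 chromosomes, down to a single
heterozygote at 1/192.  This module turns per-accession read counts (or
ingested caller VCFs) into an accessions x variants VAF matrix, intersects
call sets across callers, and produces per-variant summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "VariantKey",
    "VariantTable",
    "compute_vaf",
    "call_pooled_variants",
    "coverage_qc",
    "consensus",
    "summarize_variants",
    "cumulative_vaf_curve",
]


@dataclass(frozen=True, order=True)
class VariantKey:
    """Normalized identity of a biallelic variant on an amplicon.

    Positions are 1-based as in VCF.  ``normalized()`` trims the shared
    suffix then the shared prefix of ref/alt (left alignment for indels),
    so the same event is keyed identically across callers.
    """

    amplicon: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if not self.ref or not self.alt:
            raise ValueError("ref and alt must be non-empty")
        if self.ref == self.alt:
            raise ValueError("ref and alt must differ")

    def normalized(self) -> "VariantKey":
        ref, alt, pos = self.ref, self.alt, self.pos
        # trim common suffix, keeping at least one base on each side
        while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
            ref, alt = ref[:-1], alt[:-1]
        # trim common prefix, advancing the position
        while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
            ref, alt = ref[1:], alt[1:]
            pos += 1
        if ref == alt:
            raise ValueError(f"{self} normalizes to a non-variant")
        return VariantKey(self.amplicon, pos, ref, alt)

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 == len(self.alt)

    def __str__(self) -> str:
        return f"{self.amplicon}:{self.pos}:{self.ref}>{self.alt}"


def compute_vaf(depth_ref: int, depth_alt: int) -> float:
    """Variant allele frequency: alt reads / total reads.

    Zero total depth is a missing observation, not a frequency of zero;
    it raises so callers must handle it explicitly (the matrix builders
    store NaN and flag the cell missing).
    """
    if depth_ref < 0 or depth_alt < 0:
        raise ValueError("read depths must be nonnegative")
    total = depth_ref + depth_alt
    if total == 0:
        raise ValueError("zero total depth: VAF undefined (missing, not 0)")
    return depth_alt / total


class VariantTable:
    """Accessions x variants VAF matrix with a missingness mask.

    ``vaf`` is a DataFrame indexed by :class:`VariantKey` with one column per
    accession; uncalled cells hold 0.0 for distribution work but are marked in
    ``missing`` when they stem from zero coverage rather than reference calls.
    """

    def __init__(self, vaf: pd.DataFrame, missing: pd.DataFrame | None = None):
        bad = vaf.to_numpy(dtype=float)
        if bad.size and (np.nanmin(bad) < 0 or np.nanmax(bad) > 1):
            raise ValueError("VAF entries must lie in [0, 1]")
        self.vaf = vaf.fillna(0.0)
        if missing is None:
            missing = vaf.isna()
        self.missing = missing.astype(bool)

    @property
    def variants(self) -> list[VariantKey]:
        return list(self.vaf.index)

    @property
    def accessions(self) -> list[str]:
        return list(self.vaf.columns)

    def carriers(self, key: VariantKey) -> list[str]:
        row = self.vaf.loc[key]
        return list(row.index[row > 0])

    def to_frame(self) -> pd.DataFrame:
        out = self.vaf.copy()
        out.index = [str(k) for k in out.index]
        return out


def call_pooled_variants(
    depths: pd.DataFrame,
    alts: pd.DataFrame,
    *,
    min_alt_reads: int = 2,
    error_rate: float = 0.001,
    alpha: float = 0.05,
    min_vaf: float = 0.0,
) -> VariantTable:
    """Stand-in pooled caller operating on per-accession read counts.

    A site/accession pair is called when the alt depth reaches
    ``min_alt_reads`` and a one-sided exact binomial test of the alt count
    against the sequencing error rate rejects at ``alpha`` (exact tail, not a
    normal approximation, so single-digit alt counts behave correctly).
    Called cells carry VAF = alt/total; everything else is 0.

    ``depths``/``alts`` share index (VariantKey) and columns (accessions).
    """
    if not depths.index.equals(alts.index) or not depths.columns.equals(alts.columns):
        raise ValueError("depth and alt matrices must be aligned")
    d = depths.to_numpy(dtype=np.int64)
    a = alts.to_numpy(dtype=np.int64)
    if (a > d).any():
        raise ValueError("alt depth exceeds total depth")
    with np.errstate(invalid="ignore", divide="ignore"):
        vaf = np.where(d > 0, a / np.maximum(d, 1), 0.0)
    # P(X >= a | n=d, p=error) — survival function at a-1
    pval = stats.binom.sf(a - 1, d, error_rate)
    called = (a >= min_alt_reads) & (pval < alpha) & (vaf >= min_vaf) & (d > 0)
    out = np.where(called, vaf, 0.0)
    missing = pd.DataFrame(d == 0, index=depths.index, columns=depths.columns)
    return VariantTable(pd.DataFrame(out, index=depths.index, columns=depths.columns),
                        missing=missing)


def coverage_qc(
    depths: Sequence[int] | np.ndarray,
    min_supporting_reads: int = 20,
    target_freq: float = 0.05,
) -> float:
    """Fraction of positions deep enough to support a variant at ``target_freq``.

    A position passes when depth >= min_supporting_reads / target_freq, i.e.
    an allele at the target frequency is expected to contribute at least the
    required number of supporting reads.
    """
    d = np.asarray(depths)
    if d.size == 0:
        raise ValueError("no depths supplied")
    if not 0 < target_freq <= 1:
        raise ValueError("target_freq must be in (0, 1]")
    threshold = min_supporting_reads / target_freq
    return float(np.mean(d >= threshold))


def consensus(call_sets: Mapping[str, VariantTable]) -> dict[str, VariantTable]:
    """Intersect call sets from several callers on normalized variant keys.

    Returns, for each caller, its table restricted to the variants every
    caller reported (per-caller VAFs are kept side by side because callers
    disagree on frequency even where they agree on identity).
    """
    if len(call_sets) < 2:
        raise ValueError("need at least two call sets")
    amplicon_sets = [
        frozenset(k.amplicon for k in t.variants) for t in call_sets.values()
    ]
    if all(amplicon_sets) and not frozenset.intersection(*amplicon_sets):
        raise ValueError(
            "mismatched amplicon namespaces: call sets share no amplicon ids")
    keysets = [set(k.normalized() for k in t.variants) for t in call_sets.values()]
    common = sorted(set.intersection(*keysets))
    out = {}
    for name, table in call_sets.items():
        remap = {k.normalized(): k for k in table.variants}
        rows = [remap[k] for k in common]
        vaf = table.vaf.loc[rows]
        vaf.index = pd.Index(common)
        miss = table.missing.loc[rows]
        miss.index = pd.Index(common)
        out[name] = VariantTable(vaf, missing=miss)
    return out


def summarize_variants(table: VariantTable) -> pd.DataFrame:
    """Per-variant summary: mean VAF over carriers, max VAF, carrier count, private flag."""
    v = table.vaf.to_numpy(dtype=float)
    carrier = v > 0
    n_acc = carrier.sum(axis=1)
    with np.errstate(invalid="ignore"):
        mean_vaf = np.where(n_acc > 0, v.sum(axis=1) / np.maximum(n_acc, 1), np.nan)
    max_vaf = v.max(axis=1, initial=0.0)
    return pd.DataFrame(
        {
            "mean_vaf": mean_vaf,
            "max_vaf": max_vaf,
            "n_accessions": n_acc,
            "private": n_acc == 1,
        },
        index=pd.Index([str(k) for k in table.variants], name="variant"),
    )


def cumulative_vaf_curve(summary: pd.DataFrame, grid: np.ndarray | None = None) -> pd.DataFrame:
    """Cumulative percentage of variants with mean VAF at or below each grid value."""
    vals = summary["mean_vaf"].dropna().to_numpy()
    if grid is None:
        grid = np.round(np.arange(0.0, 1.0001, 0.01), 2)
    if vals.size == 0:
        pct = np.zeros_like(grid)
    else:
        pct = np.searchsorted(np.sort(vals), grid, side="right") / vals.size * 100.0
    return pd.DataFrame({"vaf": grid, "cumulative_pct": pct})
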