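"""CAPS assay design and per-plant validation of pooled predictions.

A CAPS (cleaved amplified polymorphic sequence) assay distinguishes the two
alleles of a variant by a restriction site the variant creates or destroys.
This module scans amplicons for IUPAC-degenerate recognition sites on both
strands, predicts digestion fragment patterns for the reference and variant
alleles, converts per-plant genotype calls to an observed allele frequency,
and compares observed frequencies against the pooled-sequencing predictions
of each caller.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .variants import VariantKey

__all__ = [
    "RestrictionEnzyme",
    "DigestPattern",
    "GenotypeCounts",
    "find_sites",
    "digest",
    "site_change",
    "observed_frequency",
    "compare_predicted_observed",
]

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class RestrictionEnzyme:
    """A restriction endonuclease named by its recognition sequence (IUPAC)."""

    name: str
    site: str

    def __post_init__(self) -> None:
        site = self.site.upper()
        if len(site) < 4:
            raise ValueError("recognition sequence must be at least 4 bp")
        if any(b not in IUPAC for b in site):
            raise ValueError(f"invalid IUPAC base in {site!r}")
        object.__setattr__(self, "site", site)

    @property
    def palindromic(self) -> bool:
        return self.site == _revcomp(self.site)


@dataclass(frozen=True)
class DigestPattern:
    """Ordered restriction fragment lengths of one allele of an amplicon."""

    allele: str
    fragments: tuple[int, ...]

    @property
    def total(self) -> int:
        return sum(self.fragments)


def _matches(seq: str, pattern: str, start: int) -> bool:
    return all(seq[start + k] in IUPAC[p] for k, p in enumerate(pattern))


def find_sites(sequence: str, enzyme: RestrictionEnzyme) -> list[int]:
    """1-based start positions of recognition-site matches on either strand.

    The pattern and its reverse complement are both scanned on the forward
    sequence; palindromic duplicates collapse to one position.
    """
    seq = sequence.upper()
    if any(b not in "ACGT" for b in seq):
        raise ValueError("sequence must be over A/C/G/T")
    patterns = {enzyme.site, _revcomp(enzyme.site)}
    hits: set[int] = set()
    for pat in patterns:
        for i in range(len(seq) - len(pat) + 1):
            if _matches(seq, pat, i):
                hits.add(i + 1)
    return sorted(hits)


def digest(sequence: str, enzyme: RestrictionEnzyme, allele: str = "ref"
           ) -> DigestPattern:
    """Fragment lengths from cutting before the first base of each site match.

    Exact within-site cut offsets vary by enzyme and do not change which
    allele a gel band identifies, so fragments are delimited at each match
    start; an uncut sequence yields a single full-length fragment.  Fragment
    lengths always sum to the sequence length.
    """
    n = len(sequence)
    cuts = [p - 1 for p in find_sites(sequence, enzyme) if p > 1]
    bounds = [0] + sorted(set(cuts)) + [n]
    frags = tuple(b - a for a, b in zip(bounds, bounds[1:]) if b > a)
    return DigestPattern(allele, frags)


def apply_variant(sequence: str, key: VariantKey) -> str:
    """The amplicon sequence carrying the alternate allele."""
    seq = sequence.upper()
    observed = seq[key.pos - 1: key.pos - 1 + len(key.ref)]
    if observed != key.ref.upper():
        raise ValueError(f"reference mismatch at {key}: amplicon has {observed!r}")
    return seq[: key.pos - 1] + key.alt.upper() + seq[key.pos - 1 + len(key.ref):]


def site_change(sequence: str, key: VariantKey, enzyme: RestrictionEnzyme
                ) -> tuple[str, DigestPattern, DigestPattern]:
    """Classify a variant's effect on an enzyme's sites: gain, loss or none.

    Both alleles are scanned over the full mutated sequence (not a window)
    so sites created across an indel's edit are caught; indels shift
    downstream coordinates implicitly through re-scanning.  Returns the
    classification and the digestion pattern of each allele.
    """
    mutated = apply_variant(sequence, key)
    n_ref = len(find_sites(sequence, enzyme))
    n_alt = len(find_sites(mutated, enzyme))
    change = "gain" if n_alt > n_ref else "loss" if n_alt < n_ref else "none"
    return (change,
            digest(sequence, enzyme, "ref"),
            digest(mutated, enzyme, "alt"))


@dataclass(frozen=True)
class GenotypeCounts:
    """Per-plant genotype tallies from a CAPS or Sanger validation assay."""

    ref_ref: int
    ref_alt: int
    alt_alt: int

    def __post_init__(self) -> None:
        if min(self.ref_ref, self.ref_alt, self.alt_alt) < 0:
            raise ValueError("genotype counts must be nonnegative")

    @property
    def n(self) -> int:
        return self.ref_ref + self.ref_alt + self.alt_alt


def observed_frequency(counts: GenotypeCounts, *, rounded: bool = False) -> float:
    """Observed allele frequency (RefAlt + 2 AltAlt) / 2n from plant genotypes.

    ``rounded`` reports the two-decimal convention used in assay tables;
    full precision is the default.
    """
    if counts.n == 0:
        raise ValueError("no plants genotyped")
    f = (counts.ref_alt + 2 * counts.alt_alt) / (2 * counts.n)
    return round(f, 2) if rounded else f


def compare_predicted_observed(predicted: Mapping[str, float], observed: float
                               ) -> tuple[list[str], dict[str, float]]:
    """Absolute deviation of each caller's predicted VAF from the observed one.

    Returns (callers achieving the minimum deviation — several when tied —
    and the per-caller deviations).
    """
    if not predicted:
        raise ValueError("need at least one caller prediction")
    dev = {name: abs(v - observed) for name, v in predicted.items()}
    best = min(dev.values())
    closest = [name for name, d in dev.items() if np.isclose(d, best)]
    return closest, dev
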