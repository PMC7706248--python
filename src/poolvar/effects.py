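"""Coding-effect classification of amplicon variants.

Each variant is placed against a simple gene model (ordered exon intervals on
an amplicon, a strand, and a CDS phase) and classified as silent, missense,
nonsense, intronic/non-coding, frameshift or in-frame indel.  Translation
uses the standard genetic code on the coding strand.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum

from Bio.Seq import Seq

from .variants import VariantKey

__all__ = ["EffectClass", "GeneModel", "annotate_variant", "annotate_table"]


class EffectClass(str, Enum):
    SILENT = "silent"
    MISSENSE = "missense"
    NONSENSE = "nonsense"
    NON_CODING = "intronic/non-coding"
    FRAMESHIFT = "frameshift-indel"
    INFRAME = "inframe-indel"


@dataclass(frozen=True)
class GeneModel:
    """Exon structure of one amplicon target.

    ``exons`` are 1-based inclusive intervals in amplicon coordinates,
    ordered and non-overlapping; they are treated as coding sequence.
    ``phase`` gives the number of bases at the 5' end of the coding-strand
    CDS that complete an upstream codon when the amplicon truncates the gene
    (0 when the CDS starts cleanly inside the amplicon).
    """

    amplicon: str
    reference: str
    exons: tuple[tuple[int, int], ...]
    strand: str = "+"
    phase: int = 0

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")
        if self.phase not in (0, 1, 2):
            raise ValueError("phase must be 0, 1 or 2")
        last = 0
        for start, end in self.exons:
            if start <= last or end < start:
                raise ValueError("exons must be ordered, non-overlapping, 1-based")
            if end > len(self.reference):
                raise ValueError("exon extends past the reference sequence")
            last = end
        object.__setattr__(self, "reference", self.reference.upper())

    def in_exon(self, pos: int) -> bool:
        return any(s <= pos <= e for s, e in self.exons)

    def cds_offset(self, pos: int) -> int:
        """0-based offset of an exonic position within the spliced plus-strand CDS."""
        off = 0
        for s, e in self.exons:
            if s <= pos <= e:
                return off + (pos - s)
            off += e - s + 1
        raise ValueError(f"position {pos} is not exonic")

    def spliced(self, sequence: str) -> str:
        return "".join(sequence[s - 1:e] for s, e in self.exons)


def _codon_change(cds_ref: str, cds_alt: str, offset: int, model: GeneModel
                  ) -> EffectClass:
    if model.strand == "-":
        cds_ref = str(Seq(cds_ref).reverse_complement())
        cds_alt = str(Seq(cds_alt).reverse_complement())
        offset = len(cds_ref) - 1 - offset
    # phase = bases at the 5' end of the coding strand completing an upstream codon
    cds_ref, cds_alt = cds_ref[model.phase:], cds_alt[model.phase:]
    offset -= model.phase
    if offset < 0:
        return EffectClass.NON_CODING
    ci = offset // 3
    ref_codon = cds_ref[ci * 3:ci * 3 + 3]
    alt_codon = cds_alt[ci * 3:ci * 3 + 3]
    if len(ref_codon) < 3 or len(alt_codon) < 3:
        return EffectClass.NON_CODING   # codon truncated by the amplicon edge
    aa_ref = str(Seq(ref_codon).translate())
    aa_alt = str(Seq(alt_codon).translate())
    if aa_alt == aa_ref:
        return EffectClass.SILENT
    if aa_alt == "*":
        return EffectClass.NONSENSE
    return EffectClass.MISSENSE


def annotate_variant(key: VariantKey, model: GeneModel) -> EffectClass:
    """Classify one variant against a gene model.

    SNVs in exons are translated codon-wise; indels in exons are frameshift
    or in-frame by length difference mod 3; everything outside exons is
    intronic/non-coding.  Indels spanning an exon-intron boundary are
    classified non-coding with a warning (no splice model).
    """
    if key.amplicon != model.amplicon:
        raise ValueError(f"variant {key} does not belong to amplicon {model.amplicon}")
    ref_seq = model.reference
    if key.pos + len(key.ref) - 1 > len(ref_seq):
        raise ValueError(f"variant {key} extends past the amplicon")
    observed = ref_seq[key.pos - 1: key.pos - 1 + len(key.ref)]
    if observed != key.ref.upper():
        raise ValueError(
            f"reference mismatch at {key}: model has {observed!r}")

    span = range(key.pos, key.pos + len(key.ref))
    exonic = [model.in_exon(p) for p in span]
    if not any(exonic):
        return EffectClass.NON_CODING
    if not all(exonic):
        warnings.warn(f"{key} spans an exon boundary; classified non-coding")
        return EffectClass.NON_CODING

    if len(key.ref) != len(key.alt):
        shift = abs(len(key.ref) - len(key.alt))
        return EffectClass.FRAMESHIFT if shift % 3 else EffectClass.INFRAME
    if not key.is_snv:
        # MNV: classify via full-codon comparison below
        pass
    cds_ref = model.spliced(ref_seq)
    mutated = ref_seq[: key.pos - 1] + key.alt.upper() + ref_seq[key.pos - 1 + len(key.ref):]
    cds_alt = model.spliced(mutated)
    return _codon_change(cds_ref, cds_alt, model.cds_offset(key.pos), model)


def annotate_table(keys: list[VariantKey], models: dict[str, GeneModel]
                   ) -> list[EffectClass]:
    """Effect class per variant; variants on amplicons without a model are non-coding."""
    out = []
    for k in keys:
        model = models.get(k.amplicon)
        out.append(EffectClass.NON_CODING if model is None
                   else annotate_variant(k, model))
    return out
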