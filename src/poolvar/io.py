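"""Readers and writers for the pipeline's file formats.

VCF 4.2 (via pysam; AD/DP/GT honored, multi-allelic records decomposed to
biallelic keys), FASTA (Biopython), Newick trees (skbio), gene models as a
GFF3 subset or BED, plus TSV/PHYLIP writers for matrices and tables.  All
coordinates are 1-based inclusive (VCF convention); BED input is converted
on read.
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO
from skbio import TreeNode

from .caps import RestrictionEnzyme
from .effects import GeneModel
from .variants import VariantKey, VariantTable

__all__ = [
    "read_vcf",
    "read_fasta",
    "write_fasta",
    "read_newick",
    "write_newick",
    "read_gene_models",
    "read_enzymes",
    "read_metadata",
    "write_distance_tsv",
    "write_distance_phylip",
]


def read_vcf(path: str | Path) -> VariantTable:
    """Read a multi-sample VCF into a VariantTable of per-accession VAFs.

    Per accession the VAF comes from the AD field (alt depth / total depth);
    when AD is absent it falls back to the alt-allele count in GT divided by
    the genotype ploidy.  Multi-allelic records are decomposed into one
    normalized biallelic key per alternate allele.  Cells with zero depth
    (or missing genotype) are flagged missing.
    """
    path = str(path)
    vf = pysam.VariantFile(path)
    samples = list(vf.header.samples)
    rows: dict[VariantKey, dict[str, float]] = {}
    missing_rows: dict[VariantKey, dict[str, bool]] = {}
    for rec in vf:
        alts = rec.alts or ()
        for ai, alt in enumerate(alts):
            if alt is None or alt in ("*", "<NON_REF>"):
                continue
            try:
                key = VariantKey(rec.chrom, rec.pos, rec.ref, alt).normalized()
            except ValueError:
                continue
            vals: dict[str, float] = {}
            miss: dict[str, bool] = {}
            for s in samples:
                sample = rec.samples[s]
                vaf, absent = _sample_vaf(sample, ai)
                vals[s] = vaf
                miss[s] = absent
            if key in rows:
                # same normalized key from several records: keep the max call
                for s in samples:
                    rows[key][s] = max(rows[key][s], vals[s])
                    missing_rows[key][s] = missing_rows[key][s] and miss[s]
            else:
                rows[key] = vals
                missing_rows[key] = miss
    keys = sorted(rows)
    vaf = pd.DataFrame([rows[k] for k in keys], index=pd.Index(keys),
                       columns=samples, dtype=float)
    missing = pd.DataFrame([missing_rows[k] for k in keys],
                           index=pd.Index(keys), columns=samples)
    return VariantTable(vaf, missing=missing)


def _sample_vaf(sample, alt_index: int) -> tuple[float, bool]:
    """(VAF, missing) for one sample and one alt allele (0-based alt index)."""
    ad = sample.get("AD")
    if ad is not None and ad[0] is not None:
        total = sum(x for x in ad if x is not None)
        if total > 0:
            return ad[alt_index + 1] / total, False
        return 0.0, True
    gt = sample.get("GT")
    if gt is None or all(a is None for a in gt):
        return 0.0, True
    called = [a for a in gt if a is not None]
    return called.count(alt_index + 1) / len(called), False


def read_fasta(path: str | Path) -> dict[str, str]:
    """Multi-record FASTA as {id: uppercase sequence}."""
    return {rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path: str | Path) -> Path:
    path = Path(path)
    with path.open("w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i:i + 70] + "\n")
    return path


def write_newick(tree: TreeNode, path: str | Path) -> Path:
    path = Path(path)
    tree.write(str(path), format="newick")
    return path


def read_newick(path: str | Path) -> TreeNode:
    return TreeNode.read(str(path), format="newick")


def read_gene_models(path: str | Path, references: dict[str, str],
                     dialect: str = "gff3") -> dict[str, GeneModel]:
    """Gene models from a GFF3 subset (exon/CDS features) or BED file.

    GFF3: 1-based inclusive; seqid = amplicon id; exon and CDS rows are
    treated alike; the phase of the first CDS row is honored.  BED: 0-based
    half-open, converted on read; column 4 names the amplicon's gene.
    Strand comes from the strand column in either dialect.
    """
    path = Path(path)
    per_amp: dict[str, dict] = {}
    for line in path.read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        f = line.rstrip("\n").split("\t")
        if dialect == "gff3":
            seqid, _, ftype, start, end = f[0], f[1], f[2], int(f[3]), int(f[4])
            if ftype.lower() not in ("exon", "cds"):
                continue
            strand = f[6] if len(f) > 6 and f[6] in "+-" else "+"
            phase = int(f[7]) if len(f) > 7 and f[7] in "012" else 0
        elif dialect == "bed":
            seqid, start, end = f[0], int(f[1]) + 1, int(f[2])
            strand = f[5] if len(f) > 5 and f[5] in "+-" else "+"
            phase = 0
        else:
            raise ValueError(f"unknown gene-model dialect {dialect!r}")
        entry = per_amp.setdefault(seqid, {"exons": [], "strand": strand,
                                           "phase": phase})
        entry["exons"].append((start, end))
    models = {}
    for amp, entry in per_amp.items():
        if amp not in references:
            raise ValueError(f"no reference sequence for amplicon {amp!r}")
        models[amp] = GeneModel(
            amplicon=amp, reference=references[amp],
            exons=tuple(sorted(entry["exons"])),
            strand=entry["strand"], phase=entry["phase"],
        )
    return models


def read_enzymes(path: str | Path) -> dict[str, RestrictionEnzyme]:
    """Restriction enzymes from a two-column TSV (name, IUPAC site)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    return {r["name"]: RestrictionEnzyme(r["name"], r["site"])
            for _, r in df.iterrows()}


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Accession metadata TSV indexed by accession code (needs a 'group' column)."""
    df = pd.read_csv(path, sep="\t")
    if "accession" not in df.columns or "group" not in df.columns:
        raise ValueError("metadata needs 'accession' and 'group' columns")
    return df.set_index("accession")


def write_distance_tsv(dist: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    dist.to_csv(path, sep="\t", float_format="%.10g")
    return path


def write_distance_phylip(dist: pd.DataFrame, path: str | Path) -> Path:
    """Square PHYLIP distance-matrix format."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"{len(dist)}\n")
        for name, row in dist.iterrows():
            vals = " ".join(f"{v:.6f}" for v in row)
            fh.write(f"{str(name):<10s} {vals}\n")
    return path
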