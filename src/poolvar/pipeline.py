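"""End-to-end orchestration: simulate or ingest, then run every analysis stage.

``run_pipeline`` chains the stages (ingest/call -> consensus -> summaries ->
population genetics -> VAF-distribution comparison -> genotype scores) on a
set of caller VCFs, or on a fully synthetic screen when given a
:class:`~poolvar.sim.SimulationConfig`.  Every output is a fixed-column TSV
or Newick file; a JSON manifest records per-stage record counts so a run can
be audited and reproduced.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .compare import (cluster_significance_matrix, export_distribution_summaries,
                      pairwise_significance)
from .genoscore import PRESETS, threshold_sensitivity
from .io import (read_metadata, read_vcf, write_distance_phylip,
                 write_distance_tsv, write_fasta, write_newick)
from .popgen import cap_infinite, nei_distance, neighbor_joining, pcoa, \
    private_allele_stats
from .sim import (CRISP_LIKE, GATK_LIKE, SNVER_LIKE, SimulationConfig,
                  emit_caller_vcf, sample_read_counts, simulate_truth)
from .variants import consensus, cumulative_vaf_curve, summarize_variants

__all__ = ["PipelineConfig", "run_pipeline"]

DEFAULT_PROFILES = (GATK_LIKE, SNVER_LIKE, CRISP_LIKE)


@dataclass
class PipelineConfig:
    """Inputs and parameters of one pipeline run.

    Either ``vcfs`` (caller name -> path) plus ``metadata_path``, or a
    ``simulation`` config from which the three emulated call sets are
    generated.  ``reference_caller`` names the call set whose VAFs feed the
    distance/comparison stages (the permissive caller, as in the study).
    """

    out_dir: Path
    vcfs: dict[str, Path] = field(default_factory=dict)
    metadata_path: Path | None = None
    simulation: SimulationConfig | None = None
    reference_caller: str = "gatk"
    alpha: float = 0.05
    bonferroni: bool = False

    def validate(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.simulation is None:
            if len(self.vcfs) < 2:
                raise ValueError("need a simulation config or >= 2 caller VCFs")
            for name, p in self.vcfs.items():
                if not Path(p).exists():
                    raise ValueError(f"VCF for caller {name!r} not found: {p}")
            if self.metadata_path is None or not Path(self.metadata_path).exists():
                raise ValueError(f"metadata table not found: {self.metadata_path}")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage, write tables/trees under ``config.out_dir``, return the manifest."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"tool": "poolvar", "version": __version__, "stages": {}}
    t_start = time.time()

    def stage(name: str, **counts) -> None:
        manifest["stages"][name] = {"elapsed_s": round(time.time() - t_start, 3),
                                    **counts}

    if config.simulation is not None:
        truth = simulate_truth(config.simulation)
        counts = sample_read_counts(truth)
        vcf_paths = {
            p.name: emit_caller_vcf(counts, p, out / f"calls_{p.name}.vcf")
            for p in DEFAULT_PROFILES
        }
        truth.truth_table().to_csv(out / "truth_sites.tsv", sep="\t", index=False)
        write_fasta(truth.references, out / "amplicons.fasta")
        metadata = truth.metadata
        metadata.to_csv(out / "metadata.tsv", sep="\t")
        stage("simulate", n_sites=len(truth.keys),
              n_accessions=len(truth.accessions))
    else:
        vcf_paths = {k: Path(v) for k, v in config.vcfs.items()}
        metadata = read_metadata(config.metadata_path)

    manifest["inputs"] = {name: {"path": str(p), "sha256": _sha256(Path(p))}
                          for name, p in vcf_paths.items()}

    call_sets = {name: read_vcf(p) for name, p in vcf_paths.items()}
    stage("ingest", **{f"n_variants_{k}": len(t.variants)
                       for k, t in call_sets.items()})

    common = consensus(call_sets)
    ref_table = common[config.reference_caller]
    stage("consensus", n_common=len(ref_table.variants))

    summary = summarize_variants(ref_table)
    summary.to_csv(out / "variant_summary.tsv", sep="\t")
    cumulative_vaf_curve(summary).to_csv(out / "vaf_cumulative.tsv",
                                         sep="\t", index=False)
    stage("summarize", n_variants=len(summary))

    vaf = ref_table.vaf
    dist = nei_distance(vaf.T)
    write_distance_tsv(dist, out / "nei_distance.tsv")
    finite = cap_infinite(dist)
    write_distance_phylip(finite, out / "nei_distance.phy")
    tree = neighbor_joining(finite)
    write_newick(tree, out / "nj_tree.nwk")
    ordination = pcoa(finite)
    ordination.coordinates.to_csv(out / "pcoa_coordinates.tsv", sep="\t")
    pd.Series(ordination.eigenvalues, name="eigenvalue").to_csv(
        out / "pcoa_eigenvalues.tsv", sep="\t", index_label="axis")
    per_acc, per_group = private_allele_stats(summary, vaf, metadata)
    per_acc.to_csv(out / "private_alleles_by_accession.tsv", sep="\t")
    per_group.to_csv(out / "private_alleles_by_group.tsv", sep="\t")
    stage("popgen", n_axes=ordination.n_axes)

    sig = pairwise_significance(vaf, alpha=config.alpha,
                                bonferroni=config.bonferroni)
    sig.to_csv(out / "pairwise_significance.tsv", sep="\t")
    _, clusters = cluster_significance_matrix(sig)
    clusters.to_csv(out / "vaf_clusters.tsv", sep="\t")
    dists = export_distribution_summaries(vaf)
    dists.drop(columns="density").to_csv(out / "vaf_distribution_summary.tsv",
                                         sep="\t")
    stage("vaf_compare", n_clusters=int(clusters.nunique()))

    trees, rf_report = threshold_sensitivity(vaf, PRESETS)
    for name, t in trees.items():
        write_newick(t, out / f"nj_genoscore_{name}.nwk")
    rf_report.to_csv(out / "threshold_sensitivity.tsv", sep="\t", index=False)
    stage("genotype_scores", n_settings=len(trees))

    manifest["total_elapsed_s"] = round(time.time() - t_start, 3)
    manifest_path = out / "manifest.json"
    tmp = manifest_path.with_suffix(".json.tmp")
    tmp.write_text(json.dumps(manifest, indent=2))
    tmp.replace(manifest_path)
    return manifest
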