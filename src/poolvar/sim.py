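"""Synthetic pooled-amplicon data with the structure of a genebank screen.

Emulates the study design the downstream analysis assumes: ~95 outcrossing
accessions of mixed improvement status (wild / landrace / historic / modern),
each pooled from 96 diploid plants and deep-sequenced over six amplicon
targets at a mean coverage near 14,000x (range roughly 3,000-30,000x).  The
generator plants three classes of variation:

* shared alleles segregating across many accessions, mostly at low pool
  frequency (the bulk of real calls sits below VAF 0.05);
* private alleles confined to a single accession, frequent and high-VAF in
  wild material, rare in cultivars;
* "hidden" alleles carried by exactly one heterozygous plant in one pool,
  the design's minimum detectable event at VAF 1/192.

Per-plant diploid genotypes are drawn Hardy-Weinberg per site (independent
sites; no linkage model), so the pool frequency is exactly the mean allele
dosage over 2n chromosomes and the truth set doubles as a genotyping ground
truth for validation-assay code.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .variants import VariantKey

__all__ = [
    "GROUPS",
    "SimulationConfig",
    "CallerProfile",
    "GATK_LIKE",
    "SNVER_LIKE",
    "CRISP_LIKE",
    "TruthSet",
    "ReadCountMatrix",
    "simulate_truth",
    "sample_read_counts",
    "emit_caller_vcf",
]

GROUPS = ("wild", "landrace", "historic", "modern")

BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic screen.

    Defaults reproduce the study conditions: 96 plants per pool, six ~600 bp
    amplicons, coverage mean 13,948x bounded by the reported extremes
    2,924x-30,275x.  ``private_allele_rate`` gives the expected number of
    private alleles per accession by germplasm group (wild accessions carry
    around six, landraces about two, cultivars under one).
    ``hidden_allele_rate`` is the expected number of single-heterozygote
    alleles per accession.  ``n_divergent`` marks that many wild accessions
    as strongly diverged (near-fixed alternate alleles at shared sites),
    mirroring a distant relative among the accessions.
    """

    n_accessions: int = 95
    n_plants_per_pool: int = 96
    n_amplicons: int = 6
    amplicon_length: int = 600
    n_shared_sites: int = 40
    carrier_prob: float = 0.5
    private_allele_rate: Mapping[str, float] = field(
        default_factory=lambda: {"wild": 6.0, "landrace": 2.0,
                                 "historic": 0.5, "modern": 0.5}
    )
    hidden_allele_rate: float = 1.0
    group_fractions: Mapping[str, float] = field(
        default_factory=lambda: {"wild": 0.11, "landrace": 0.37,
                                 "historic": 0.36, "modern": 0.16}
    )
    n_divergent: int = 1
    coverage_mean: float = 13948.0
    coverage_min: float = 2924.0
    coverage_max: float = 30275.0
    error_rate: float = 0.001
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_accessions", "n_plants_per_pool", "n_amplicons",
                     "amplicon_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 <= self.error_rate < 0.5:
            raise ValueError("error_rate must lie in [0, 0.5)")
        if not (self.coverage_min <= self.coverage_mean <= self.coverage_max):
            raise ValueError("need coverage_min <= coverage_mean <= coverage_max")
        if self.n_divergent < 0 or self.n_divergent > self.n_accessions:
            raise ValueError("n_divergent out of range")
        unknown = set(self.private_allele_rate) - set(GROUPS)
        if unknown:
            raise ValueError(f"unknown germplasm groups: {sorted(unknown)}")

    def rng(self, stage: str) -> np.random.Generator:
        """Deterministic per-stage substream derived from the master seed."""
        stage_key = int.from_bytes(stage.encode(), "little") % (2**31)
        return np.random.default_rng(np.random.SeedSequence((self.seed, stage_key)))


@dataclass(frozen=True)
class CallerProfile:
    """Thresholds an emulated caller applies before reporting a variant."""

    name: str
    min_alt_reads: int
    min_vaf: float = 0.0


# Three emulated call sets with nested-ish stringency so they overlap but
# differ, the permissive one being largest (as the real callers did).
GATK_LIKE = CallerProfile("gatk", min_alt_reads=3, min_vaf=0.002)
CRISP_LIKE = CallerProfile("crisp", min_alt_reads=8, min_vaf=0.004)
SNVER_LIKE = CallerProfile("snver", min_alt_reads=25, min_vaf=0.008)


@dataclass
class TruthSet:
    """Ground truth of one simulated screen.

    ``dosage`` holds per-plant alt-allele dosages (accession x site x plant,
    values 0/1/2); ``freq`` is the exact pool allele frequency, i.e. mean
    dosage over 2 x n_plants chromosomes.  ``sites`` records each variant's
    class (shared / private / hidden) and owner accession where applicable.
    """

    config: SimulationConfig
    metadata: pd.DataFrame           # index accession, columns: group, divergent
    sites: pd.DataFrame              # index VariantKey order, columns below
    keys: list[VariantKey]
    dosage: np.ndarray               # (n_accessions, n_sites, n_plants) int8
    references: dict[str, str]       # amplicon id -> sequence

    @property
    def accessions(self) -> list[str]:
        return list(self.metadata.index)

    @property
    def freq(self) -> pd.DataFrame:
        """Exact pool allele frequencies, sites x accessions."""
        n2 = 2 * self.config.n_plants_per_pool
        f = self.dosage.sum(axis=2).T / n2
        return pd.DataFrame(f, index=pd.Index(self.keys), columns=self.accessions)

    def truth_table(self) -> pd.DataFrame:
        out = self.sites.copy()
        out.insert(0, "variant", [str(k) for k in self.keys])
        return out


@dataclass
class ReadCountMatrix:
    """Simulated pileup depths per accession and site (biallelic model)."""

    keys: list[VariantKey]
    accessions: list[str]
    depth: pd.DataFrame              # total reads, sites x accessions
    alt: pd.DataFrame                # alt-supporting reads

    def __post_init__(self) -> None:
        d = self.depth.to_numpy()
        a = self.alt.to_numpy()
        if (d < 0).any() or (a < 0).any() or (a > d).any():
            raise ValueError("invalid read counts")

    @property
    def ref(self) -> pd.DataFrame:
        return self.depth - self.alt


def _assign_groups(cfg: SimulationConfig, rng: np.random.Generator) -> list[str]:
    counts = {g: int(round(cfg.group_fractions.get(g, 0.0) * cfg.n_accessions))
              for g in GROUPS}
    # round-off goes to the largest group
    short = cfg.n_accessions - sum(counts.values())
    counts[max(counts, key=counts.get)] += short
    groups: list[str] = []
    for g in GROUPS:
        groups.extend([g] * counts[g])
    return groups[: cfg.n_accessions]


def simulate_truth(config: SimulationConfig) -> TruthSet:
    """Draw a ground-truth population: site map, per-plant genotypes, pool freqs."""
    rng = config.rng("truth")
    n_acc, n_pl = config.n_accessions, config.n_plants_per_pool

    groups = _assign_groups(config, rng)
    codes = [f"{chr(ord('A') + i // 12)}{i % 12 + 1}" for i in range(n_acc)]
    divergent = np.zeros(n_acc, dtype=bool)
    wild_idx = [i for i, g in enumerate(groups) if g == "wild"]
    for i in wild_idx[: config.n_divergent]:
        divergent[i] = True
    metadata = pd.DataFrame({"group": groups, "divergent": divergent},
                            index=pd.Index(codes, name="accession"))

    references = {
        f"amp{j + 1}": "".join(rng.choice(BASES, size=config.amplicon_length))
        for j in range(config.n_amplicons)
    }
    amp_ids = list(references)

    # reserve distinct positions per amplicon for all site classes
    n_private = rng.poisson([config.private_allele_rate.get(g, 0.0) for g in groups])
    n_hidden = rng.poisson(np.full(n_acc, config.hidden_allele_rate))
    n_sites = config.n_shared_sites + int(n_private.sum()) + int(n_hidden.sum())
    per_amp = [n_sites // config.n_amplicons + (1 if j < n_sites % config.n_amplicons else 0)
               for j in range(config.n_amplicons)]
    if max(per_amp, default=0) > config.amplicon_length:
        raise ValueError("amplicons too short for the requested number of sites")
    positions: list[tuple[str, int]] = []
    for amp, k in zip(amp_ids, per_amp):
        pos = rng.choice(config.amplicon_length, size=k, replace=False) + 1
        positions.extend((amp, int(p)) for p in sorted(pos))
    rng.shuffle(positions)

    keys: list[VariantKey] = []
    site_rows: list[dict] = []
    pop_freq = np.zeros((n_acc, n_sites))

    def new_key(kind: str, owner: str | None) -> None:
        amp, pos = positions[len(keys)]
        ref = references[amp][pos - 1]
        alt = str(rng.choice([b for b in "ACGT" if b != ref]))
        keys.append(VariantKey(amp, pos, ref, alt))
        site_rows.append({"kind": kind, "owner": owner})

    # shared alleles: each accession carries with carrier_prob at a low,
    # right-skewed frequency; divergent accessions are near-fixed alt.
    for s in range(config.n_shared_sites):
        new_key("shared", None)
        carry = rng.random(n_acc) < config.carrier_prob
        f = np.where(carry, rng.beta(0.8, 8.0, size=n_acc), 0.0)
        f[divergent] = rng.uniform(0.85, 1.0, size=divergent.sum())
        pop_freq[:, s] = f

    s = config.n_shared_sites
    for i, (code, g) in enumerate(zip(codes, groups)):
        for _ in range(int(n_private[i])):
            new_key("private", code)
            if g == "wild":
                pop_freq[i, s] = rng.beta(2.0, 2.5)      # mean ~0.44, spread wide
            else:
                pop_freq[i, s] = rng.beta(0.3, 4.0)      # low mean, tiny median
            s += 1
    hidden_start = s
    for i, code in enumerate(codes):
        for _ in range(int(n_hidden[i])):
            new_key("hidden", code)
            s += 1

    # Hardy-Weinberg per-plant dosages; hidden sites get exactly one het
    dosage = np.zeros((n_acc, n_sites, n_pl), dtype=np.int8)
    geno = rng.binomial(2, pop_freq[:, :, None], size=(n_acc, n_sites, n_pl))
    dosage[:, :hidden_start, :] = geno[:, :hidden_start, :]
    s = hidden_start
    for i, code in enumerate(codes):
        for _ in range(int(n_hidden[i])):
            plant = int(rng.integers(n_pl))
            dosage[i, s, plant] = 1
            s += 1

    sites = pd.DataFrame(site_rows)
    sites.insert(0, "alt", [k.alt for k in keys])
    sites.insert(0, "ref", [k.ref for k in keys])
    sites.insert(0, "pos", [k.pos for k in keys])
    sites.insert(0, "amplicon", [k.amplicon for k in keys])
    return TruthSet(config, metadata, sites, keys, dosage, references)


def _truncated_lognormal(rng: np.random.Generator, mean: float, lo: float,
                         hi: float, size: int) -> np.ndarray:
    """Log-normal truncated to [lo, hi] with expected value ``mean``.

    sigma is set so the bounds sit near +/-2 sigma of the log distribution;
    mu is then solved so the truncated distribution's mean equals ``mean``
    (plain moment-matching would undershoot after truncation).
    """
    if hi == lo:
        return np.full(size, lo)
    from scipy import optimize, stats as sps

    sigma = max(np.log(hi / lo) / 4.0, 1e-6)

    def truncated_mean(mu: float) -> float:
        a, b = (np.log(lo) - mu) / sigma, (np.log(hi) - mu) / sigma
        z = sps.norm.cdf(b) - sps.norm.cdf(a)
        upper = sps.norm.cdf(b - sigma) - sps.norm.cdf(a - sigma)
        return np.exp(mu + sigma**2 / 2) * upper / max(z, 1e-300)

    mu0 = np.log(mean) - sigma**2 / 2.0
    mu = optimize.brentq(lambda m: truncated_mean(m) - mean,
                         mu0 - 2.0, mu0 + 2.0)
    out = rng.lognormal(mu, sigma, size=size)
    bad = (out < lo) | (out > hi)
    while bad.any():
        out[bad] = rng.lognormal(mu, sigma, size=int(bad.sum()))
        bad = (out < lo) | (out > hi)
    return out


def sample_read_counts(truth: TruthSet, config: SimulationConfig | None = None
                       ) -> ReadCountMatrix:
    """Draw sequencing depths and alt-read counts for every accession x site.

    Depth is truncated log-normal within the configured coverage bounds; alt
    reads are binomial with success probability f(1-e) + (1-f)e, folding the
    symmetric per-base error rate into the true pool frequency f.
    """
    cfg = config or truth.config
    rng = cfg.rng("reads")
    n2 = 2 * cfg.n_plants_per_pool
    f = truth.dosage.sum(axis=2) / n2                       # (acc, site)
    depth = _truncated_lognormal(
        rng, cfg.coverage_mean, cfg.coverage_min, cfg.coverage_max, f.size
    ).reshape(f.shape).round().astype(np.int64)
    p = f * (1 - cfg.error_rate) + (1 - f) * cfg.error_rate
    alt = rng.binomial(depth, p)
    idx = pd.Index(truth.keys)
    return ReadCountMatrix(
        truth.keys,
        truth.accessions,
        depth=pd.DataFrame(depth.T, index=idx, columns=truth.accessions),
        alt=pd.DataFrame(alt.T, index=idx, columns=truth.accessions),
    )


def emit_caller_vcf(counts: ReadCountMatrix, profile: CallerProfile,
                    path: str | Path) -> Path:
    """Write a VCF 4.2 with per-accession AD/DP, filtered per caller profile.

    An accession's call is reported when its alt depth and VAF clear the
    profile's thresholds; non-called accessions carry AD=(depth,0) so the
    record stays rectangular.  Sites no accession supports are omitted, so
    different profiles on the same counts yield overlapping but distinct
    call sets (a permissive profile emits a superset of a stricter one).
    """
    path = Path(path)
    depth = counts.depth.to_numpy()
    alt = counts.alt.to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"):
        vaf = np.where(depth > 0, alt / np.maximum(depth, 1), 0.0)
    called = (alt >= profile.min_alt_reads) & (vaf >= profile.min_vaf) & (depth > 0)

    amplicons = sorted({k.amplicon for k in counts.keys})
    lines = [
        "##fileformat=VCFv4.2",
        f"##source=poolvar-sim:{profile.name}",
        '##INFO=<ID=NS,Number=1,Type=Integer,Description="Accessions called">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
    ]
    lines += [f"##contig=<ID={a}>" for a in amplicons]
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(counts.accessions))
    order = sorted(range(len(counts.keys)),
                   key=lambda i: (counts.keys[i].amplicon, counts.keys[i].pos))
    n_records = 0
    for i in order:
        if not called[i].any():
            continue
        k = counts.keys[i]
        samples = []
        for j in range(len(counts.accessions)):
            d, a = int(depth[i, j]), int(alt[i, j])
            if called[i, j]:
                samples.append(f"0/1:{d - a},{a}:{d}")
            else:
                samples.append(f"0/0:{d},0:{d}")
        lines.append(
            f"{k.amplicon}\t{k.pos}\t.\t{k.ref}\t{k.alt}\t.\tPASS\t"
            f"NS={int(called[i].sum())}\tGT:AD:DP\t" + "\t".join(samples)
        )
        n_records += 1
    path.write_text("\n".join(lines) + "\n")
    return path
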