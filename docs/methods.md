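# Methods

## The measurement model

Each accession is represented by a pool of *n* = 96 diploid plants, so a
biallelic site has 2*n* = 192 chromosomes in the pool.  The within-accession
population allele frequency is estimated by the variant allele frequency

VAF = d_alt / (d_ref + d_alt),

the fraction of alternate-supporting reads at the site.  Zero total depth is
treated as *missing*, never as VAF 0: a reference call and an uncovered
position are different observations, and the two are tracked separately
(missingness mask on the VAF matrix).  The smallest biologically meaningful
event is one heterozygous plant in the pool, VAF = 1/192 ≈ 0.0052; at
14,000× coverage such an allele contributes ≈73 alternate reads, which is
why the depth QC rule requires ≥ 20/f reads to support an allele at
frequency f (400× for a 5 % allele).

### Stand-in pooled caller

External callers are ingested as VCFs.  When calling from read counts
directly, a site/accession is reported when (i) d_alt ≥ `min_alt_reads` and
(ii) an exact one-sided binomial tail P(X ≥ d_alt | depth, error_rate) falls
below α.  The exact tail (not a normal approximation) matters because the
decision boundary sits at single-digit to low-double-digit alt counts.

### Multi-caller consensus

Variant identity is the normalized key (amplicon, pos, ref, alt): shared
suffix trimmed, then shared prefix trimmed with the position advanced, which
left-aligns indels so the same event matches across callers.  The consensus
set is the intersection of normalized keys; per-caller VAFs are kept side by
side, since callers that agree on identity still disagree on frequency.
Multi-allelic records are decomposed into one biallelic key per alternate
allele on read.

## Population genetics on VAF

Each locus is treated as biallelic with frequencies (p, 1−p), p the pool
VAF.  Nei's (1972) standard distance is

D = −ln( J_xy / √(J_x·J_y) ),  J_x = mean(p² + q²),  J_xy = mean(p_x p_y + q_x q_y),

averaged over loci.  Pairs with J_xy = 0 (possible only when the pair is
oppositely fixed at every locus) get D = ∞; before tree building the policy
`cap_infinite` replaces ∞ by 10× the largest finite entry (configurable) and
the exact value is preserved in the distance TSV.  Loci where one accession
was not called enter with p = 0 (monomorphic reference), i.e. all common
variants are used for every pair rather than restricting to jointly called
loci.

Neighbor Joining uses the Studier–Keppler Q criterion; ties in Q break to
the lowest index pair so trees are bit-reproducible.  Negative branch
lengths are retained by default (`clamp_negative=True` clamps to zero).  The
result is returned as a trifurcating-rooted `skbio.TreeNode`, the standard
Newick representation of an unrooted binary tree.  On additive matrices NJ
recovers the generating tree exactly; the tests verify this against
explicit topology enumeration on 4–5 taxa.

PCoA is the classical construction: B = −½·J·D²·J with J the centering
operator, symmetric eigendecomposition, coordinates = eigenvector·√λ for
eigenvalues above a relative tolerance of 1e−10.  Negative eigenvalues
(non-Euclidean distances) are reported but carry no coordinates.

Private alleles are variants with carrier count exactly 1 in the analyzed
set.  Group summaries (wild / landrace / historic / modern) report the mean
count per accession and mean/median VAF of private alleles.

## Two-part Wilcoxon test

VAF vectors are strongly zero-inflated (an accession simply lacks most
variants), so pairwise comparisons use the two-part construction
(Lachenbruch): B is the pooled-variance two-proportion z-statistic on the
fractions of zeros; W is the Wilcoxon rank-sum statistic on the nonzero
values, standardized by the tie-corrected normal approximation; X² = B² + W²
is referred to χ² with 2 df.  When exactly one part is computable — no zeros
in either sample, or no nonzero values in one — the available part alone is
referred to χ² with 1 df, which makes the no-zeros case collapse exactly to
the plain tie-corrected rank-sum test (verified to 1e−6 against an
independent implementation).  When neither part is computable the samples
are indistinguishable: p = 1, flagged degenerate.  No multiplicity
correction is applied across the pairwise matrix by default (raw α = 0.05
decisions); a Bonferroni option exists.

The binary significance matrix is clustered by complete linkage using the
matrix itself as the dissimilarity; flat clusters are cut at height 0.5,
i.e. just below 1, so accessions share a cluster exactly when they are
mutually non-different.  The cut height is a design choice — any value in
(0, 1) gives the same flat clusters for a binary dissimilarity under
complete linkage.

## Genotype scores

Treating a pool as a single individual: VAF < L → 0, VAF ≥ U → 1, otherwise
2, for (L, U) ∈ {(0.3, 0.7), (0.4, 0.6), (0.2, 0.8)}.  The published rule
leaves VAF exactly equal to L unassigned ("< L → 0", "greater than L → 2");
the implementation maps [L, U) → 2 so the function is total on [0, 1].
Scores feed plain (non-squared) Euclidean distances and NJ; sensitivity to
the heterozygote band is quantified by the Robinson–Foulds distance between
the three trees (the original analysis compared trees visually).

## CAPS assays

Recognition sites (IUPAC-degenerate, ≥ 4 bp) are scanned on the forward
sequence and its reverse complement, deduplicated for palindromes.
Fragments are delimited at the first base of each site match: exact
within-site cut offsets differ per enzyme and never change which allele a
gel band identifies, so fragment lengths are accurate to within the site
length.  Both alleles are re-scanned over the full mutated sequence, so
indels implicitly shift downstream sites and edits that *create* a site
across the junction are caught.  Observed allele frequency from per-plant
genotyping is (RefAlt + 2·AltAlt)/(2n), reported at full precision and at
the two-decimal table convention.

The bundled validation table ships printed per-caller predictions, observed
frequencies, plant counts and heterozygote counts; homozygous-variant counts
are reconstructed as (round(obs·2n) − het)/2 and left NA for the single row
no integer count reproduces (the row is kept for the closest-caller tally,
which needs only printed values).

## Synthetic screens

The generator reproduces the study conditions as defaults: 96 plants/pool,
six ~600 bp amplicons, coverage mean 13,948× bounded to [2,924×, 30,275×],
per-base error 0.001.  Three classes of variation are planted:

* **shared** alleles: each accession carries with probability 0.5 at a
  Beta(0.8, 8) frequency (right-skewed; most calls below VAF 0.05);
* **private** alleles: Poisson counts per accession with group means wild 6,
  landrace 2, historic 0.5, modern 0.5; wild private frequencies are
  Beta(2, 2.5) (mean ≈ 0.44), others Beta(0.3, 4) (low mean, tiny median);
* **hidden** alleles: exactly one heterozygous plant in one pool,
  pool frequency exactly 1/192 by construction.

One wild accession is marked divergent and drawn at 0.85–1.0 alternate
frequency at shared sites, emulating a distant self-pollinating relative
that is near-homozygous for non-reference alleles.  Per-plant genotypes are
Hardy–Weinberg per site with independent sites (no linkage model); the pool
frequency equals the realized mean dosage over 2n chromosomes exactly.
Depth is log-normal with σ set from the bound ratio and μ solved so the
*truncated* mean equals the configured mean; alt reads are
Binomial(depth, f(1−e) + (1−f)e) with symmetric substitution error e.  There
is no read-level simulation: no PCR amplification bias, no position- or
motif-dependent error, no indel sequencing error (indels exist only as
alleles), no mapping artifacts.  Passing tests therefore demonstrate the
statistical machinery under the idealized sampling model, not robustness to
real MiSeq error structure.  The per-base error default (0.001) is a
placeholder for an unreported instrument profile.

Emulated callers are threshold profiles (min alt reads 3/8/25, min VAF
0.002/0.004/0.008) applied to one read-count realization, yielding
overlapping but distinct VCF call sets whose intersection exercises the
consensus logic; they do not model the algorithmic differences between real
callers.

Randomness flows from a single master seed through named per-stage
substreams (`SeedSequence((seed, stage))`), so truth generation and read
sampling can be re-run independently and all outputs are bit-reproducible.

## Problem sizes

Tests and the acceptance script use 12-accession screens (3 per germplasm
group, 6 amplicons, ≈100–170 sites) and 1,000-replicate null simulations at
n = 300 for test calibration — sizes chosen so the full analysis chain,
including every pairwise test on 12 accessions, completes in seconds while
leaving Monte-Carlo error well inside the asserted bands.

## Known limitations

* Within-accession Hardy–Weinberg with independent sites ignores linkage
  and inbreeding; real outcrossing populations violate both mildly.
* Effect classification handles SNVs codon-wise and classifies multi-base
  substitutions by the codon of their first base; variants spanning
  exon–intron boundaries are conservatively non-coding (no splice model).
  Protein-level deleteriousness scoring is out of scope; an external flag
  column can be carried through summaries.
* Nei's D on VAFs inherits the pool-seq assumption that read sampling is
  binomial from the pool; amplification bias would bias D.
* The NJ implementation targets ≤ a few hundred taxa (dense O(n³)); it is
  not meant for large phylogenies.
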