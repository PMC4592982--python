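# Methods

`germscan` re-implements, as a tested pipeline, the statistical workflow used
to fingerprint a large inbred germplasm collection from array SNP genotypes:
locus QC, redundancy detection, neighbor-joining clustering, linkage
disequilibrium (LD) and haplotype-block analysis, Fst selection scans, and a
dichotomized case-control genome-wide association study (GWAS). Every stage
exploits one property of the material: accessions of a highly selfing species
are near-fully homozygous, so each accession's genotype is read as a single
observed haplotype (one haploid allele per locus) rather than a diploid
genotype to be phased.

## Genotype model and QC

Calls are `{REF_HOM, HET, ALT_HOM, MISSING}` in an accessions x loci `int8`
matrix. QC proceeds in a fixed order:

1. **Bad-call filter.** A locus is removed when its combined heterozygous +
   missing call rate across all accessions exceeds 0.1 (strictly; a locus at
   exactly 0.1 is kept), or when fewer than two homozygous states are
   observed (monomorphic). The rate is computed before het masking, matching
   the order in which the original workflow applied the two rules.
2. **Het masking.** Residual heterozygous calls — in an inbred collection
   they are mostly genotyping artifacts or residual heterozygosity — are set
   to missing. The operation is idempotent.
3. **MAF filter** (LD/block/GWAS stages only). Allele frequencies count one
   allele per accession over non-missing calls; loci with minor allele
   frequency < 5% are removed, boundary inclusive.

Coordinates are 1-based; region-class maps (euchromatic vs heterochromatic
compartments) are ingested as BED with 0-based half-open intervals and
converted explicitly.

## Similarity and redundancy

Similarity of two accessions = identical calls / loci called in both. Pairs
with no shared called locus are flagged undefined rather than scored.
Redundancy groups are single-linkage connected components over edges with
similarity ≥ a threshold (1.0 for "identical", 0.999 for "near-identical"):
membership requires similarity to *at least one* other member, which is
exactly single linkage. Deduplication keeps one deterministic representative
per group (lexicographically smallest id). The blocked matrix-product
implementation is contract-tested against the naive per-pair loop.

## Clustering

Distances are pairwise-deletion p-distances (1 − similarity); no
evolutionary-model correction is applied because distances feed a topology,
not divergence-time estimates. Neighbor joining follows Saitou–Nei with two
determinism conventions: Q-matrix ties break on the smallest (i, j) index
pair, and a negative branch length is clamped to zero with the deficit moved
to its sister branch so exported Newick lengths are nonnegative. On additive
matrices the output reproduces the input patristic distances exactly; the
test suite cross-checks splits against scikit-bio's independent NJ.

## LD statistics and pair classification

For a locus pair, jointly called accessions give 2x2 haplotype counts
directly. From sample frequencies: D = pAB − pA·pB, r² = D²/(pA pa pB pb),
D′ = |D|/Dmax. The D′ confidence interval uses the normalized-likelihood
percentile method: alleles are relabelled so D ≥ 0, the multinomial
likelihood of the four counts is evaluated on a D′ grid of step 0.001 with
allele frequencies fixed at sample estimates, normalized to unit mass, and
the 5th/95th percentiles of that curve are reported. Pairs are classified
strong-LD (upper bound > 0.98 and lower bound > 0.7), strong-recombination
(upper bound < 0.9), inconclusive, or uninformative (no joint calls or
monomorphic in the pair's subsample). Pairs are evaluated within 1-Mb
windows along each chromosome.

Two numerical notes, found while validating against an independently coded
grid oracle: the 5th percentile for perfectly associated counts of moderate
size sits slightly below 0.98 (0.971 at 100/0/0/100 — still comfortably
strong-LD), and a boundary maximum-likelihood estimate (D′ = 0 or 1) can lie
a few grid steps outside the percentile interval; containment of the point
estimate is guaranteed only for interior estimates.

Decay curves are binned means of r² by distance (default 10 kb bins in
euchromatin, 50 kb in heterochromatin, chosen to resolve the different decay
scales of the two compartments); empty bins are flagged absent, never zero.
The half-decay distance is the midpoint of the first bin whose mean falls to
half the curve's maximum — an empirical rule on the binned curve, not a
parametric fit — so it is quantized to the bin width. Where orderings across
populations are compared, means over replicate simulations are used so a
single quantized curve cannot tie by chance.

## Haplotype blocks

A candidate block [i..j] on one chromosome requires (a) the outermost pair
strong-LD, (b) among informative pairs within the interval (strong-LD +
strong-recombination, including the outer pair) a strong-LD fraction ≥ 0.95,
and (c) span ≤ 1 Mb (blocks cannot contain pairs that were never computed).
Candidates are accepted greedily by decreasing bp span, ties leftmost,
skipping overlaps; the greedy result is verified against brute-force
enumeration on all small instances. Block span is last-minus-first member
position; a block straddling the compartment boundary takes the class of the
majority of its members. Haplotypes are tallied over accessions fully called
within the block.

Cross-population sharing is computed over SNP *pairs*: restricted to loci
present in both maps, the universe is every pair co-blocked in either map,
concordant pairs are co-blocked in both, and sharing % =
100·concordant/universe — symmetric by construction. Annotation contrasts:
genes are "in blocks" when their start position falls inside a block
(expected counts assume uniform gene density per compartment); in-block
recombination is total cM between each block's outermost mapped SNPs over
total block bp, compared with the same ratio over the whole compartment.

## Fst scan

Per-locus Fst between two populations uses Hudson's estimator on
haploid-coded samples: Fst = 1 − Hw/Hb with Hw the average within-population
heterozygosity (with the n/(n−1) small-sample factor) and
Hb = pA(1−pB) + pB(1−pA). Hudson's form was chosen over AMOVA-style
machinery because it is closed-form, well-defined for haploid-coded inbred
data, and the downstream use (genome mean, SD, outlier threshold) is
estimator-agnostic; absolute per-locus values can differ from other
estimators. Slightly negative estimates are retained in the mean/SD. The
genome-wide threshold is mean + 1.959964·SD (two-tailed 5% normal quantile),
reported to three decimals; this construction reproduces published
threshold arithmetic exactly from the corresponding means and SDs.
Significant loci are merged into candidate regions when consecutive
significant loci are ≤ 500 kb apart (configurable; no canonical definition
of "region" exists).

## Case-control GWAS

Seed weight (g/100 seeds) is dichotomized — ≥ 20 case, ≤ 10 control,
otherwise excluded — so that year/location variation in the quantitative
records cannot flip a label. Stratification uses K user-chosen clusters,
either supplied externally or from k-means on the top 10 principal
components of the mean-imputed allele-dosage matrix. The per-locus statistic
is a Cochran–Mantel–Haenszel-type sum over strata of 2x2 allele-by-phenotype
tables (haploid allele counts, no continuity correction):
X² = (Σ(aₖ−Eₖ))²/ΣVₖ with Vₖ = R1ₖR2ₖC1ₖC2ₖ/Nₖ³. The N³ variance (instead
of the textbook N²(N−1)) is a deliberate choice: it makes the K = 1
statistic identical to the classical allelic Pearson chi-square, an
equivalence the suite verifies on random tables; for realistic stratum sizes
the two differ by under 1%. Zero-margin strata contribute nothing. Genomic
control divides statistics by λ = median(X²)/0.4549364, clamped at 1;
significance requires −log10(adjusted p) > 3 (strict).

## Synthetic collection generator

The generator produces the structures the pipeline assumes, at desk scale,
from a single seeded `numpy` generator:

* **Haplotype hierarchy.** A few deep "proto" haplotypes (default 6) →
  founder pool (default 30) drawn as proto mosaics → populations drawn as
  founder mosaics. The proto layer gives even the wild population fine-scale
  haplotype structure (without it, 30 independent founder haplotypes carry
  all four gametes at almost every pair and no D′ blocks can form).
* **Nested bottlenecks.** Landrace founders are a 12-haplotype subset of the
  founder pool; cultivar founders a 6-haplotype subset of those. Combined
  with decreasing per-bp founder-switch rates (6e-5 wild, 5e-6 landrace,
  1.5e-6 cultivar; heterochromatin at 0.25x), LD length and block size
  increase wild → landrace → cultivar, the diversity-reduction signature the
  pipeline is meant to detect.
* **Planted truth.** Recombination-free intervals with exactly two
  complementary haplotypes (recoverable blocks); duplicate accessions copied
  after noise so zero-corruption duplicates are bit-identical; selected loci
  forced toward fixation in cultivars (Fst outliers); three causal loci
  chosen at moderate cultivated-pool frequency with effects (9, 7, 6) g on a
  base of 7 g and noise SD 1.5 g, so cases (≥ 20 g) need two causal alleles
  and controls (≤ 10 g) none. Het/missing noise at 0.5%/2%.
* **Defaults** are 2 chromosomes x 6 Mb x 300 loci and 100/100/70
  accessions — small enough that the full pipeline runs in seconds yet large
  enough that every recovery statistic is stable across seeds.

What the generator does *not* emulate: coalescent genealogical noise,
mutation/genotyping asymmetries, real genome coordinates, linked selection,
or phenotype-environment interaction. Passing tests therefore demonstrate
correctness of the statistical machinery and qualitative behavior under the
planted model, not calibration on any real collection; collection-scale
headline numbers (population sizes, block totals, half-decay distances in
real coordinates) are outside what a desk-scale simulation can reproduce.

## Numerical and degenerate-input conventions

* Undefined similarity (no shared calls) is flagged, never 0; distance
  construction refuses such pairs.
* Uninformative LD pairs (monomorphic subsample) carry NaN statistics and
  are excluded from curves.
* Loci monomorphic for the same allele in both populations are excluded from
  Fst (never 0/0).
* λ is clamped at 1; a warning is issued under 100 tested loci.
* All tie-breaks (NJ joins, block acceptance, representatives) are
  deterministic, so outputs are reproducible bit-for-bit for a fixed seed.
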