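# Methods

## Scope and data model

`vitikin` operates on diploid biallelic SNP genotypes held in a
`GenotypeMatrix`: per sample and locus an alt-allele dosage in {0, 1, 2}
with an explicit missing state, optional per-call read depth, and optional
phased haplotypes.  Coordinates are 1-based as in VCF; loci are identified
by (chrom, pos) and alleles are taken as written — no strand flipping, no
multiallelic decomposition.  Every summary statistic (call rate, allele
frequency, heterozygosity, all pairwise counts) is computed over called
genotypes only, because differential missingness is the defining feature
of mixed ancient/modern panels.

## Kinship (KING-robust)

For a pair (i, j), over sites called in both,

    phi = (N_het,het − 2 N_opp_hom) / (N_het_i + N_het_j).

This heterozygote-concordance form needs no allele frequencies and is
therefore robust to population structure in the panel.  Under Mendelian
inheritance the expectations are: clones 1/2 (exactly, for identical
genotypes), outcross parent–offspring 1/4, parent vs one-generation-selfed
offspring 1/3 (at parent-heterozygous sites the offspring is heterozygous
with probability 1/2 and opposite homozygotes are impossible, giving
(H/2)/(H + H/2)).  IBS0 = N_opp_hom / N_compared is exactly zero for
parent–offspring and duplicate pairs.

Classification uses the conventional powers-of-two ranges: phi > 0.354
duplicate/clone; (0.177, 0.354] first degree, split into parent–offspring
(IBS0 ≤ `ibs0_po_max`, default 0.01) and other first degree; (0.0884,
0.177] second degree; (0.0442, 0.0884] third degree; otherwise unrelated.
All cut-offs are configurable.  Pairs with fewer than `min_compared`
overlapping calls (default 200) are reported as undetermined rather than
classified from noise — sparse ancient samples make this guard necessary.
Note that the estimator is known to go negative for pairs whose
heterozygosity differs structurally (e.g. an inbred sample against an
outbred panel); the classification thresholds only use the positive range.

## Descent tests

**Containment.**  A violating allele is an offspring allele copy absent
from the parent genotype at the same site: parent hom-ref vs offspring
dosage d contributes d violations, parent hom-alt contributes 2 − d, a
heterozygous parent can never be violated.  Counting per allele copy (not
per genotype) makes the violation rate directly comparable to a per-allele
sequencing error rate: v violations over n compared sites is a rate
v / (2n).  The allowance can be given as a count or as a rate (default
0.5%), converted to a count by flooring.  `directionality` runs the test
both ways: mutual containment indicates clones, one-way containment
indicates descent from that parent alone, neither indicates an unrelated
pair (under Hardy–Weinberg, unrelated pairs violate at a rate far above
any plausible error allowance).

**Selfing generations.**  Each selfing generation halves expected
heterozygosity, so with heterozygote counts restricted to sites called in
both samples (the conservative choice — differential missingness cannot
then bias the ratio), g_hat = round(log2(het_parent / het_offspring)),
floored at 0.  `compatible` flags whether the observed ratio is within a
multiplicative tolerance (default ±25%) of (1/2)^g_hat.  The estimator is
undefined (flagged) when either count is zero.

**Haplotype matching.**  Each offspring haplotype is compared to both
parent haplotypes per chromosome over sites phased in both samples, and
the argmin mismatch fraction is reported.  No recombination modelling:
whole-chromosome best match only, which suffices for the short
chromosome-scale checks the tool is used for.

## IBD segment sharing

Segment files are whitespace-delimited with columns
`id1 hap1 id2 hap2 chrom start end lod` (1-based, end-inclusive, lengths in
base pairs); rows with LOD ≤ `min_lod` (default 3) are dropped and
malformed rows are skipped with a logged count.  The column mapping is
configurable for dialect drift.  Per-pair totals sum segment lengths over
all four haplotype pairings.  Probabilistic IBD detection and phasing are
consumed, never reimplemented; the built-in `naive_segments` finder emits
maximal runs of identical alleles on error-free phased data and exists as
a ground-truth oracle for the simulator.

Heatmap orderings: `hclust` applies average-linkage agglomeration on the
distance 1 − shared/max(shared) (a documented, configurable choice — any
monotone transform of sharing would do); `closeness` places the focal
samples first and ranks the rest by descending mean shared length with the
focal set.

## Polygenic colour score

Berry colour is treated as an ordinal grade (white 0, gray 1, rose 2,
red 3, black 4) with an additive genetic basis.  Dosage coding counts
copies of the stated effect allele (either ref or alt; relabelling alleles
with a sign-flipped beta is a no-op up to a constant).  Loci with missing
calls are skipped — no imputation — and a sample with fewer than
`min_loci` usable loci is flagged undefined rather than scored from a
subset too small to compare.  Percentile placement reports the fraction of
each reference category scoring strictly below the sample, with ties
counted half so the placement is order-independent and monotone in the
score.

`fit_allele_effects` is a deliberately simple per-locus least-squares
slope of grade on dosage with Bonferroni selection; it validates the
scoring machinery on simulated panels and is not an association-study
replacement (no covariates, no kinship correction).

## Dataset construction

Filters apply in a fixed, auditable order: per-call depth mask (calls
below `min_depth`, default 5, in the named sequenced-sample subset are set
missing — loci are not dropped for depth) → locus call rate (default
0.75) → sample call rate (default 0.60) → MAF (default 0.03 with its own
0.80 call-rate requirement, computed on the calls surviving the earlier
stages).  A `FilterReport` records counts removed at each stage.

The dual-dataset strategy trades loci against focal (ancient) samples:
`wide` drops any focal sample that fails the sample-call-rate bar on the
locus-filtered matrix, then filters; `deep` restricts to loci called in
every focal sample, keeps all focal samples (exempt from the sample
stage), then filters.  On sparse-focal panels wide retains at least as
many loci as deep; adversarial missingness patterns could in principle
reverse the inequality, which is why the counts are always reported.

## Simulator

The simulator generates what the analyses assume and no more:

* founders are unrelated Hardy–Weinberg diploids; per-locus alt
  frequencies default to uniform on [0.05, 0.95] (a flat folded-SFS proxy
  for an ascertained SNP-array panel, which is depleted of rare alleles);
* loci are spread evenly over 19 chromosomes (the grape karyotype) at a
  fixed 1 kb spacing, so segment logic has coordinates to work with;
* gametes form per chromosome as a two-state Markov walk over the parent's
  haplotypes with switch probability `crossover_rate` between adjacent
  loci.  The default 0.5 makes every locus an independent Mendelian draw
  (the regime in which the kinship expectations concentrate); small rates
  transmit long intact blocks for IBD testing.  No genetic map realism is
  attempted;
* pedigree events are `cross` (one gamete per parent), `self` (two
  independent gametes from one parent) and `clone` (identical copy);
  founder-haplotype ancestry labels propagate with every allele, giving
  exact IBD ground truth;
* degradation applies, in order, a symmetric per-allele ref/alt flip with
  probability `error_rate` (default 0.33%, the scale at which ancient
  grape calls are typically audited), then per-sample call masking, then
  Poisson(mean_depth) per-call depths (0 for missing calls).  The error
  model is symmetric because the containment arithmetic it feeds counts
  per allele copy; no deamination-profile (C→T) asymmetry is simulated;
* colour grades are latent additive scores plus Gaussian noise, clipped to
  [0, 4] and mapped to the nearest grade, ties rounding half up (an
  explicit convention; nothing downstream depends on the tie direction).

What the simulator does **not** emulate: linkage disequilibrium between
founders, recombination maps, aDNA damage patterns, genotype-calling
artefacts correlated across samples, and reference-panel ascertainment
bias.  Tests that pass on simulated data therefore demonstrate the
correctness of the estimators under their stated assumptions, not their
robustness to every real-data pathology.

## Numerical and testing choices

* One `numpy` Generator per entry point, seeded explicitly; identical
  seeds give bit-identical matrices and pipeline outputs.
* The exact-equivalence test between the naive segment finder and the
  ancestry ground truth uses a maximally heterozygous founder (one all-ref
  and one all-alt haplotype): allele identity then holds *iff* ancestry
  matches, so identity-by-state coincidences cannot extend true blocks and
  the comparison is exact, segment for segment.  On generic founders the
  finder's output is a superset of the truth by construction.
* Monte-Carlo checks run at 10,000 loci where binomial noise puts the
  kinship estimates within ±0.02 of their expectations; parameter-recovery
  checks use 200 estimator replicates (50 selfing chains × generations
  0–3) and a 500-sample panel for the colour-effect slope.  These sizes
  keep the default suite around ten seconds while leaving the acceptance
  margins wide.
* Undefined quantities (zero denominators, empty comparisons) are returned
  as NaN/None with an explicit flag, never silently coerced.

## Known limitations

* Kinship categories assume roughly outbred panels; sustained inbreeding
  shifts phi (the selfed-offspring 1/3 is the first example) and the
  powers-of-two ranges should be re-examined for heavily selfed material.
* The containment allowance treats errors as independent across allele
  copies; systematic callers' artefacts violate that.
* `hclust` leaf order depends on the stated distance transform; it is a
  display choice, not an inference.
* The per-locus colour-effect estimator ignores linkage and population
  structure; effect tables for real inference should come from a proper
  association analysis.
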