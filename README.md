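# vitikin

Kinship, descent and berry-colour inference for sparse grapevine SNP panels.

Ancient and feral grapevines leave genotypes that are sparse (high
missingness, low read depth) yet still carry strong signals of identity and
parentage: grape is clonally propagated for centuries, and selfed or
clone-bred offspring show characteristic genotype patterns.  `vitikin`
implements the pairwise analyses that exploit those signals on diploid
biallelic SNP data — e.g. comparing archaeological grape pips against a
modern cultivar panel — together with a pedigree simulator that generates
panels with the same statistical structure for testing and power analysis.

## What it computes

**KING-robust kinship.**  For each sample pair, over the sites called in
both:

    phi = (N_Aa,Aa − 2 · N_AA,aa) / (N_Aa^i + N_Aa^j)

where `N_Aa,Aa` counts sites heterozygous in both samples and `N_AA,aa`
counts opposite homozygotes.  The estimator uses no population allele
frequencies, so it is robust to structure in the reference panel.
Expected values: 1/2 for duplicates/clones, 1/4 for outcross
parent–offspring, 1/3 for a parent versus its one-generation-selfed
offspring.  `IBS0 = N_AA,aa / N_compared` is exactly 0 for parent–offspring
and duplicate pairs, separating them from other first-degree relatives.
Pairs are classified with the conventional powers-of-two thresholds (all
configurable).

**Directional genotype containment.**  An offspring can be homozygous where
its only parent is heterozygous, but can never carry an allele the parent
lacks.  Counting offspring allele copies absent from the parent genotype —
with a small allowance for sequencing error — and running the test in both
directions distinguishes "B descends from A alone" from clone pairs
(mutual containment) and unrelated pairs (neither).

**Selfing-generation estimate.**  Each selfing or clone-by-clone breeding
generation halves expected heterozygosity, so
`g = round(log2(het_parent / het_offspring))` estimates the number of
generations separating the pair.

**IBD segment sharing.**  Haplotype-level identity-by-descent segment calls
(refined-IBD-style tab files) are summed into per-pair shared-base-pair
matrices, with heatmap orderings by hierarchical clustering or by average
closeness to a focal sample set.  An exact-match segment finder provides a
desk-scale oracle for error-free phased data.

**Polygenic berry-colour score.**  With a table of per-locus effect-allele
weights in colour-grade units (white=0 … black=4), each sample's score is
the sum of effect-allele dosage × weight over its called loci, interpreted
by percentile placement within a reference panel of known colour.

**Dataset construction.**  Call-rate / depth / minor-allele-frequency
filters, plus the dual-dataset strategy for sparse panels: a "wide" dataset
maximising SNP count (dropping the sparsest focal samples) and a "deep"
dataset keeping every focal sample at the cost of loci.

## Worked example

Simulate a 10-sample panel (8 founders, a clone of `F000`, a selfed
offspring of `F001` named `ANC1`), then estimate kinship and test descent:

```sh
printf 'child\tkind\tparents\nCLONE\tclone\tF000\nANC1\tself\tF001\n' > ped.tsv
vitikin simulate --n-founders 8 --n-loci 3000 --error-rate 0 \
    --missing-rate 0.02 --seed 42 --pedigree ped.tsv -o demo
vitikin kinship demo.vcf --min-compared 100 -o kinship.tsv
vitikin descent demo.vcf F001 ANC1
```

The kinship table flags exactly the two planted relationships:

```
id1   id2    n_compared  n_het_het  n_opp_hom  phi     ibs0  category
F000  CLONE  2873        1058       0          0.5     0.0   duplicate/clone
F001  ANC1   2901        577        0          0.3370  0.0   parent-offspring
```

The clone pair sits at phi = 1/2 with no opposite homozygotes; `ANC1` vs its
selfing parent sits near the 1/3 expectation, again with IBS0 = 0.  The
descent report confirms the direction and the selfing depth:

```json
{
  "verdict": "a_contains_b",
  "selfing": {
    "het_parent": 1135,
    "het_offspring": 577,
    "ratio": 0.5084,
    "g_hat": 1,
    "compatible": true
  }
}
```

Every `ANC1` allele is contained in `F001` (but not vice versa), and the
offspring carries roughly half the parent's heterozygous sites — one
selfing generation.

`vitikin run-all config.yaml` drives the whole pipeline (filters, dual
datasets, kinship tables, IBD heatmaps, descent reports, colour scores)
from a single YAML config; see `vitikin --help` for the subcommands.

## Documentation

`docs/methods.md` describes the models, the simulator's scope, numerical
choices and known limitations.
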